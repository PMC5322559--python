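"""Rule-based classification of genomes into Se-utilization traits.

Three selenophosphate-dependent traits are known in prokaryotes, each
defined by the joint presence of its complete marker machinery:

* **Sec** (selenocysteine decoding): SelA + SelB + SelD
* **SeU** (2-selenouridine tRNA modification): SelD + YbbB
* **SeCofactor** (Se-containing cofactor): SelD + YqeB + YqeC

SelD (selenophosphate synthetase) supplies the Se donor to all three and is
the universal signature of Se utilization.  A genome carrying SelD but none
of the trait-specific markers is an *orphan SelD* — a possible pointer to
unknown Se chemistry.  Partial machineries (e.g. SelA + SelD without SelB)
are reported diagnostically but never counted as the trait.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .compendium import Compendium, PresenceMatrix

SELD = "SelD"

#: The trait markers plus the other known Se-related families (Sec lyase
#: recycles Sec-derived selenium; SirA-like is a known Se-associated redox
#: family): the default island seed set for genomic-context scans.
KNOWN_SE_FAMILIES = ("SelA", "SelB", "SelD", "YbbB", "YqeB", "YqeC",
                     "sec_lyase", "sirA_like")


@dataclass(frozen=True)
class TraitDefinition:
    """A trait is assigned iff ALL of its required families are present."""

    name: str
    required_families: frozenset[str]

    def __post_init__(self) -> None:
        if not self.required_families:
            raise ValueError(f"trait {self.name!r} has no required families")


def default_traits() -> tuple[TraitDefinition, ...]:
    return (
        TraitDefinition("Sec", frozenset({"SelA", "SelB", "SelD"})),
        TraitDefinition("SeU", frozenset({"SelD", "YbbB"})),
        TraitDefinition("SeCofactor", frozenset({"SelD", "YqeB", "YqeC"})),
    )


def trait_specific_families(defs: Sequence[TraitDefinition],
                            seld_family: str = SELD) -> frozenset[str]:
    """Union of required families across traits, minus SelD — the exclusion
    list for orphan-SelD calling, derived from the definitions so
    user-defined traits extend it automatically."""
    out: set[str] = set()
    for d in defs:
        out |= d.required_families
    out.discard(seld_family)
    return frozenset(out)


@dataclass
class TraitProfile:
    """Per-genome trait assignments plus SelD/orphan flags."""

    traits: dict[str, frozenset[str]]  # genome_id -> assigned trait names
    selD_present: dict[str, bool]
    orphan_selD: dict[str, bool]
    trait_names: tuple[str, ...]

    @property
    def genome_ids(self) -> list[str]:
        return list(self.traits)

    def has_any_trait(self, genome_id: str) -> bool:
        return bool(self.traits[genome_id])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gid in self.traits:
            row = {"genome_id": gid,
                   "selD_present": self.selD_present[gid],
                   "orphan_selD": self.orphan_selD[gid]}
            for t in self.trait_names:
                row[t] = t in self.traits[gid]
            rows.append(row)
        return pd.DataFrame(rows).set_index("genome_id")

    def to_tsv(self, path) -> None:
        self.to_frame().astype(int).to_csv(path, sep="\t")


def classify_traits(matrix: PresenceMatrix,
                    defs: Sequence[TraitDefinition] | None = None,
                    seld_family: str = SELD) -> TraitProfile:
    """Assign traits to every genome of a presence matrix.

    Each trait is evaluated independently: assigned iff all its required
    families are present.  Orphan SelD = SelD present, no trait-specific
    family present (hence no trait assigned).
    """
    defs = tuple(defs) if defs is not None else default_traits()
    needed = set().union(*(d.required_families for d in defs)) | {seld_family}
    missing = sorted(needed - set(matrix.family_ids))
    if missing:
        raise KeyError(f"presence matrix lacks required family columns: {missing}")
    specific = trait_specific_families(defs, seld_family)
    traits: dict[str, frozenset[str]] = {}
    seld: dict[str, bool] = {}
    orphan: dict[str, bool] = {}
    df = matrix.df
    for gid in matrix.genome_ids:
        present = {f for f in needed if bool(df.at[gid, f])}
        assigned = frozenset(d.name for d in defs if d.required_families <= present)
        traits[gid] = assigned
        seld[gid] = seld_family in present
        orphan[gid] = seld[gid] and not (present & specific)
    return TraitProfile(traits=traits, selD_present=seld, orphan_selD=orphan,
                        trait_names=tuple(d.name for d in defs))


def flag_orphan_selD(matrix: PresenceMatrix,
                     defs: Sequence[TraitDefinition] | None = None,
                     seld_family: str = SELD) -> set[str]:
    """Genomes with SelD but no trait-specific marker family."""
    profile = classify_traits(matrix, defs, seld_family)
    return {gid for gid, flag in profile.orphan_selD.items() if flag}


def partial_traits(matrix: PresenceMatrix,
                   defs: Sequence[TraitDefinition] | None = None) -> pd.DataFrame:
    """Diagnostic table of incomplete machineries: genomes carrying some
    but not all required families of a trait, with the missing ones."""
    defs = tuple(defs) if defs is not None else default_traits()
    rows = []
    df = matrix.df
    for gid in matrix.genome_ids:
        for d in defs:
            have = {f for f in d.required_families if f in df.columns and bool(df.at[gid, f])}
            if have and have != d.required_families:
                rows.append({"genome_id": gid, "trait": d.name,
                             "present": ";".join(sorted(have)),
                             "missing": ";".join(sorted(d.required_families - have))})
    return pd.DataFrame(rows, columns=["genome_id", "trait", "present", "missing"])


@dataclass
class OverlapSummary:
    """Venn-region counts over the defined traits plus the orphan count.

    ``regions`` maps each nonempty trait subset (frozenset of names) to the
    number of genomes with exactly that trait combination; the regions
    partition the trait-positive genomes.
    """

    trait_names: tuple[str, ...]
    regions: dict[frozenset, int]
    orphan_count: int
    n_trait_positive: int

    def region(self, *names: str) -> int:
        return self.regions.get(frozenset(names), 0)

    def to_dict(self) -> dict:
        labels = {}
        for subset, count in self.regions.items():
            ordered = [t for t in self.trait_names if t in subset]
            labels["&".join(ordered)] = count
        return {"regions": labels, "orphan_selD": self.orphan_count,
                "n_trait_positive": self.n_trait_positive}


def venn_counts(profile: TraitProfile) -> OverlapSummary:
    """Mutually exclusive overlap-region counts (7 regions for the three
    default traits)."""
    names = profile.trait_names
    regions: dict[frozenset, int] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            regions[frozenset(combo)] = 0
    n_pos = 0
    for gid, assigned in profile.traits.items():
        if assigned:
            regions[frozenset(assigned)] += 1
            n_pos += 1
    orphans = sum(profile.orphan_selD.values())
    assert sum(regions.values()) == n_pos
    return OverlapSummary(trait_names=names, regions=regions,
                          orphan_count=orphans, n_trait_positive=n_pos)


def taxon_distribution(profile: TraitProfile, compendium: Compendium,
                       level: int = 0, min_genomes: int = 1) -> pd.DataFrame:
    """Per-taxon occurrence table (one row per taxon at the given lineage
    depth): genome count, SelD count, per-trait counts, orphan count and
    the corresponding fractions.

    Genomes whose lineage is shorter than ``level + 1`` are tallied under
    their last available taxon and flagged (``truncated_lineage``).  Taxa
    with fewer than ``min_genomes`` genomes are dropped — mirrors hiding
    single-genome phyla in occurrence figures.
    """
    rows: dict[str, dict] = {}
    for gid, genome in compendium.genomes.items():
        if gid not in profile.traits:
            continue
        lineage = genome.lineage
        if not lineage:
            taxon, truncated = "unclassified", True
        elif level < len(lineage):
            taxon, truncated = lineage[level], False
        else:
            taxon, truncated = lineage[-1], True
        row = rows.setdefault(taxon, {"taxon": taxon, "n_genomes": 0, "n_selD": 0,
                                      "n_orphan_selD": 0, "truncated_lineage": False,
                                      **{f"n_{t}": 0 for t in profile.trait_names}})
        row["n_genomes"] += 1
        row["n_selD"] += profile.selD_present[gid]
        row["n_orphan_selD"] += profile.orphan_selD[gid]
        row["truncated_lineage"] |= truncated
        for t in profile.traits[gid]:
            row[f"n_{t}"] += 1
    table = pd.DataFrame(rows.values())
    if table.empty:
        return table
    table = table[table["n_genomes"] >= min_genomes].reset_index(drop=True)
    for col in ["n_selD", "n_orphan_selD"] + [f"n_{t}" for t in profile.trait_names]:
        table[col.replace("n_", "frac_", 1)] = table[col] / table["n_genomes"]
    return table.sort_values("taxon").reset_index(drop=True)


def habitat_summary(profile: TraitProfile, compendium: Compendium) -> pd.DataFrame:
    """Fraction of aquatic / nonaquatic genomes carrying >= 1 trait.

    Genomes of unknown habitat are excluded from denominators; a habitat
    class with no genomes is absent from the table (not reported as 0%).
    Raises if every genome's habitat is unknown.
    """
    counts: dict[str, dict] = {}
    any_known = False
    for gid, genome in compendium.genomes.items():
        if gid not in profile.traits or genome.habitat == "unknown":
            continue
        any_known = True
        row = counts.setdefault(genome.habitat,
                                {"habitat": genome.habitat, "n_genomes": 0, "n_with_trait": 0})
        row["n_genomes"] += 1
        row["n_with_trait"] += profile.has_any_trait(gid)
    if not any_known:
        raise ValueError("all genomes have unknown habitat")
    table = pd.DataFrame(counts.values()).sort_values("habitat").reset_index(drop=True)
    table["percent_with_trait"] = 100.0 * table["n_with_trait"] / table["n_genomes"]
    return table
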