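"""Locus-level statistics: family abundances, RN-effector co-occurrence,
restricted association, background frequencies, phage aggregation and
tree-annotation export.

Throughout, an "associated RN" is an RN annotation that survived the
conserved-residue screen (``screen_status != fail``): candidates lacking
an absolutely conserved residue are treated as removed false positives.
A locus counts once per family even when it carries duplicate genes of
the same family.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core_model import Locus, RNAnnotation, SignalMapping, default_signal_mapping


@dataclass(frozen=True)
class NetworkNode:
    node_id: str
    kind: str  # "RN" | "effector"
    signal: str


@dataclass(frozen=True)
class NetworkEdge:
    rn: str
    effector: str
    weight: int


@dataclass
class BipartiteNetwork:
    """RN-effector co-occurrence graph; same-kind edges are forbidden
    (within-role co-occurrences are removed to highlight RN-effector
    links)."""

    nodes: list[NetworkNode] = field(default_factory=list)
    edges: list[NetworkEdge] = field(default_factory=list)

    def __post_init__(self) -> None:
        kind = {n.node_id: n.kind for n in self.nodes}
        for e in self.edges:
            if kind.get(e.rn) == kind.get(e.effector):
                raise ValueError(
                    f"edge ({e.rn}, {e.effector}) joins two same-kind nodes"
                )


@dataclass
class CooccurrenceSummary:
    """All locus-level RN statistics for one annotated dataset."""

    n_loci: int
    family_instances: dict[str, int]  # RN genes per family
    family_loci: dict[str, int]  # loci containing the family
    n_rn_positive_loci: int
    n_multi_rn_loci: int
    multi_rn_loci: list[tuple[str, tuple[str, ...]]]
    rn_by_effector: pd.DataFrame  # loci containing both families
    restricted_assoc: dict[str, tuple[int, int, float]]
    n_rn_loci_without_effector: int
    frac_rn_instances_in_effector_loci: float


def summarize(loci: Sequence[Locus]) -> CooccurrenceSummary:
    """Count RN instances, RN-positive and multi-RN loci, and the
    RN-by-effector co-occurrence matrix.

    Instance counts are per gene; locus counts are per family per locus.
    The instance-level fraction found in effector-containing loci is
    reported alongside the locus-level effector-less count, since the two
    denominators differ.
    """
    family_instances: dict[str, int] = {}
    family_loci: dict[str, int] = {}
    multi_rn: list[tuple[str, tuple[str, ...]]] = []
    n_rn_positive = 0
    n_no_effector = 0
    n_instances_total = 0
    n_instances_with_eff = 0
    rn_fams_seen: set[str] = set()
    eff_fams_seen: set[str] = set()
    pair_counts: dict[tuple[str, str], int] = {}
    for loc in loci:
        rns = loc.passing_rns()
        eff_fams = loc.effector_families_present()
        eff_fams_seen |= eff_fams
        for r in rns:
            family_instances[r.family] = family_instances.get(r.family, 0) + 1
            n_instances_total += 1
            if eff_fams:
                n_instances_with_eff += 1
        rn_fams = {r.family for r in rns}
        rn_fams_seen |= rn_fams
        for f in rn_fams:
            family_loci[f] = family_loci.get(f, 0) + 1
        if rn_fams:
            n_rn_positive += 1
            if not eff_fams:
                n_no_effector += 1
        if len(rns) > 1:
            multi_rn.append(
                (loc.locus_id, tuple(sorted(r.family for r in rns)))
            )
        for rf in rn_fams:
            for ef in eff_fams:
                pair_counts[(rf, ef)] = pair_counts.get((rf, ef), 0) + 1
    rn_idx = sorted(rn_fams_seen)
    eff_idx = sorted(eff_fams_seen)
    matrix = pd.DataFrame(0, index=rn_idx, columns=eff_idx, dtype=int)
    for (rf, ef), n in pair_counts.items():
        matrix.loc[rf, ef] = n
    return CooccurrenceSummary(
        n_loci=len(loci),
        family_instances=family_instances,
        family_loci=family_loci,
        n_rn_positive_loci=n_rn_positive,
        n_multi_rn_loci=len(multi_rn),
        multi_rn_loci=sorted(multi_rn),
        rn_by_effector=matrix,
        restricted_assoc=restricted_association(loci),
        n_rn_loci_without_effector=n_no_effector,
        frac_rn_instances_in_effector_loci=(
            n_instances_with_eff / n_instances_total if n_instances_total else math.nan
        ),
    )


def restricted_association(
    loci: Sequence[Locus],
) -> dict[str, tuple[int, int, float]]:
    """Per effector family: proportion of loci that also encode an RN,
    restricted to loci with exactly one effector and at most one RN.

    Families observed only outside the restricted set are reported with
    denominator 0 and an undefined (NaN) proportion, never dropped.
    """
    with_rn: dict[str, int] = {}
    totals: dict[str, int] = {}
    all_families: set[str] = set()
    for loc in loci:
        all_families |= loc.effector_families_present()
        if len(loc.effectors) != 1 or len(loc.passing_rns()) > 1:
            continue
        fam = loc.effectors[0].family
        totals[fam] = totals.get(fam, 0) + 1
        if loc.passing_rns():
            with_rn[fam] = with_rn.get(fam, 0) + 1
    out: dict[str, tuple[int, int, float]] = {}
    for fam in sorted(all_families):
        n = totals.get(fam, 0)
        k = with_rn.get(fam, 0)
        out[fam] = (k, n, k / n if n else math.nan)
    return out


def build_network(
    loci: Sequence[Locus], signal_mapping: SignalMapping | None = None
) -> BipartiteNetwork:
    """Bipartite RN-effector graph weighted by co-occurrence counts.

    Edge weight (r, e) = number of loci containing both families;
    zero-weight pairs are omitted.  RN nodes carry signal cA4 (all
    characterized RN families here degrade cA4); effector nodes carry
    their mapped signal.
    """
    mapping = signal_mapping or default_signal_mapping()
    pair_counts: dict[tuple[str, str], int] = {}
    rn_fams: set[str] = set()
    eff_fams: set[str] = set()
    for loc in loci:
        rfams = {r.family for r in loc.passing_rns()}
        efams = loc.effector_families_present()
        rn_fams |= rfams
        eff_fams |= efams
        for rf in rfams:
            for ef in efams:
                pair_counts[(rf, ef)] = pair_counts.get((rf, ef), 0) + 1
    nodes = [NetworkNode(f, "RN", "cA4") for f in sorted(rn_fams)] + [
        NetworkNode(f, "effector", mapping.signal_for(f)) for f in sorted(eff_fams)
    ]
    edges = [
        NetworkEdge(rn=rf, effector=ef, weight=n)
        for (rf, ef), n in sorted(pair_counts.items())
        if n > 0
    ]
    return BipartiteNetwork(nodes=nodes, edges=edges)


def background_frequency(
    genome_rns: Mapping[str, Sequence[RNAnnotation]],
    loci: Sequence[Locus],
    family: str,
) -> float | None:
    """Fraction of family-carrying genomes that lack any type III locus.

    ``genome_rns`` maps genome id -> genome-wide screened RN annotations
    (no locus restriction; screen failures excluded here).  Returns
    ``None`` when no genome carries the family.
    """
    genomes_with_locus = {loc.genome_id for loc in loci}
    carriers = {
        gid
        for gid, anns in genome_rns.items()
        if any(a.family == family and a.screen_status != "fail" for a in anns)
    }
    if not carriers:
        return None
    return len(carriers - genomes_with_locus) / len(carriers)


def phage_family_counts(
    phage_rns: Mapping[str, Sequence[RNAnnotation]],
) -> dict[str, int]:
    """Per RN family, number of distinct phage genomes with >= 1 passing
    instance (genome-level dedup: two genes in one phage count once)."""
    genomes_per_family: dict[str, set[str]] = {}
    for phage_id, anns in phage_rns.items():
        for a in anns:
            if a.screen_status != "fail":
                genomes_per_family.setdefault(a.family, set()).add(phage_id)
    return {f: len(g) for f, g in sorted(genomes_per_family.items())}


def tree_annotation(
    newick: str | os.PathLike,
    loci: Sequence[Locus],
    rn_families: Sequence[str] = ("Crn1", "Crn2", "Crn3", "Csx15", "Csx16", "Csx20"),
) -> pd.DataFrame:
    """Leaf-annotation table for a Cas10 tree (the concentric-ring export).

    Leaf labels are Cas10 gene ids.  Each row carries the locus subtype,
    inferred signal(s), one presence column per RN family, and a flag for
    cyclase-lacking Cas10s (the "red dot" class).  Leaves without a
    matching locus get explicit NA values, never dropped.  Duplicate leaf
    labels abort.
    """
    import dendropy

    tree = dendropy.Tree.get(
        path=os.fspath(newick),
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
        suppress_leaf_node_taxa=True,
    )
    labels = [leaf.label for leaf in tree.leaf_node_iter()]
    dupes = sorted({l for l in labels if labels.count(l) > 1})
    if dupes:
        raise ValueError(f"duplicate leaf labels: {', '.join(dupes)}")
    by_anchor = {loc.cas10.gene.gene_id: loc for loc in loci}
    rows = []
    for label in labels:
        loc = by_anchor.get(label)
        if loc is None:
            row: dict[str, object] = {
                "leaf": label,
                "subtype": pd.NA,
                "signals": pd.NA,
                "cyclase_absent": pd.NA,
            }
            row.update({f: pd.NA for f in rn_families})
        else:
            present = loc.rn_families_present()
            row = {
                "leaf": label,
                "subtype": loc.subtype,
                "signals": ";".join(sorted(loc.signals)) or "none",
                "cyclase_absent": int(not loc.cas10.has_cyclase),
            }
            row.update({f: int(f in present) for f in rn_families})
        rows.append(row)
    cols = ["leaf", "subtype", "signals", *rn_families, "cyclase_absent"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# TSV exports


def write_summary_tables(
    summary: CooccurrenceSummary, out_dir: str | os.PathLike
) -> None:
    """family_counts.tsv, restricted_association.tsv and multi_rn.tsv."""
    os.makedirs(out_dir, exist_ok=True)
    fams = sorted(set(summary.family_instances) | set(summary.family_loci))
    pd.DataFrame(
        {
            "family": fams,
            "n_instances": [summary.family_instances.get(f, 0) for f in fams],
            "n_loci": [summary.family_loci.get(f, 0) for f in fams],
        }
    ).to_csv(os.path.join(out_dir, "family_counts.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "effector_family": f,
                "n_with_rn": k,
                "n_restricted_loci": n,
                "proportion": p,
            }
            for f, (k, n, p) in summary.restricted_assoc.items()
        ],
        columns=["effector_family", "n_with_rn", "n_restricted_loci", "proportion"],
    ).to_csv(
        os.path.join(out_dir, "restricted_association.tsv"), sep="\t", index=False
    )
    pd.DataFrame(
        [
            {"locus_id": lid, "rn_families": ";".join(fams_)}
            for lid, fams_ in summary.multi_rn_loci
        ],
        columns=["locus_id", "rn_families"],
    ).to_csv(os.path.join(out_dir, "multi_rn.tsv"), sep="\t", index=False)


def write_phage_counts(
    counts: Mapping[str, int], path: str | os.PathLike
) -> None:
    pd.DataFrame(
        {"family": list(counts), "n_phage_genomes": list(counts.values())}
    ).to_csv(path, sep="\t", index=False)
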