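"""Assemble Cas10-anchored type III CRISPR-Cas loci.

The anchor is any gene with a Cas10 profile hit below the e-value ceiling.
From the anchor, the cas operon span is grown by chaining neighbouring
genes that carry cas-core profile hits across intergenic gaps of at most
``chain_gap`` bp.  The search neighborhood extends the span by ``window``
bp (6 kbp by default) on each side, clipped at contig ends; every gene
overlapping the neighborhood by at least 1 bp is a locus member.  The
6 kbp distance is measured from the cas-span edges, not from the Cas10
gene alone, and strand is ignored for membership.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from .core_model import (
    Cas10Annotation,
    DomainHit,
    FamilyCatalogue,
    GeneFeature,
    Interval,
    Locus,
    interval_gap,
    intervals_overlap,
)

DEFAULT_WINDOW = 6000  # bp each side of the cas span
DEFAULT_CHAIN_GAP = 500  # max intergenic gap within the cas operon


def _best_hit(
    hits: Sequence[DomainHit], wanted: set[str], ceiling: float
) -> DomainHit | None:
    cands = [h for h in hits if h.family_id in wanted and h.evalue <= ceiling]
    if not cands:
        return None
    return min(cands, key=lambda h: (-h.bitscore, h.evalue, h.family_id))


def find_cas10_anchors(
    genes: Sequence[GeneFeature],
    hits_by_protein: Mapping[str, Sequence[DomainHit]],
    catalogue: FamilyCatalogue,
    evalue_ceiling: float = 1e-4,
) -> list[GeneFeature]:
    """Genes with >= 1 Cas10-profile hit at or below the e-value ceiling.

    Each anchor is reported once even when several Cas10 profiles hit it.
    """
    anchors = []
    for g in genes:
        for h in hits_by_protein.get(g.gene_id, ()):
            if catalogue.is_cas10_profile(h.family_id) and h.evalue <= evalue_ceiling:
                anchors.append(g)
                break
    return anchors


def build_cas_span(
    anchor: GeneFeature,
    genes: Sequence[GeneFeature],
    hits_by_protein: Mapping[str, Sequence[DomainHit]],
    catalogue: FamilyCatalogue,
    chain_gap: int = DEFAULT_CHAIN_GAP,
    evalue_ceiling: float = 1e-4,
) -> Interval:
    """Smallest interval covering the anchor and every cas-core gene
    reachable from it by intergenic gaps <= ``chain_gap``.

    Only genes on the anchor's contig participate.  The chain is the
    transitive closure of the gap relation restricted to cas-core genes,
    seeded at the anchor.
    """
    cas_genes = [
        g
        for g in genes
        if g.contig_id == anchor.contig_id
        and (
            g.gene_id == anchor.gene_id
            or any(
                h.family_id in catalogue.cas_core_families
                and h.evalue <= evalue_ceiling
                for h in hits_by_protein.get(g.gene_id, ())
            )
        )
    ]
    cas_genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
    idx = next(i for i, g in enumerate(cas_genes) if g.gene_id == anchor.gene_id)
    # BFS transitive closure over the gap graph restricted to cas genes
    reached = {idx}
    frontier = [idx]
    while frontier:
        i = frontier.pop()
        for j, g in enumerate(cas_genes):
            if j not in reached and interval_gap(cas_genes[i].interval, g.interval) <= chain_gap:
                reached.add(j)
                frontier.append(j)
    chained = [cas_genes[i] for i in reached]
    return (min(g.start for g in chained), max(g.end for g in chained))


def build_neighborhood(
    cas_span: Interval, contig_length: int, window: int = DEFAULT_WINDOW
) -> Interval:
    """Extend the cas span by ``window`` bp each side, clipped to the contig."""
    return (max(1, cas_span[0] - window), min(contig_length, cas_span[1] + window))


def merge_overlapping_loci(loci: list[Locus]) -> list[Locus]:
    """Merge loci whose cas spans overlap (same contig) into one locus.

    The merged span is the union; the anchor becomes the Cas10 with the
    best recorded bit score (carried in the annotation order: the caller
    supplies loci sorted by descending anchor score so the first locus of
    each merged group keeps its anchor).  Neighborhoods must be re-derived
    by the caller, since the contig length is not known here.
    """
    by_contig: dict[tuple[str, str], list[Locus]] = {}
    for loc in loci:
        by_contig.setdefault((loc.genome_id, loc.contig_id), []).append(loc)
    merged: list[Locus] = []
    for group in by_contig.values():
        group.sort(key=lambda l: l.cas_span)
        current: list[Locus] = []
        for loc in group:
            if current and intervals_overlap(current[-1].cas_span, loc.cas_span):
                prev = current[-1]
                keeper, other = prev, loc
                # anchor of the merged locus = best-scoring Cas10
                if other.cas10.gene.gene_id != keeper.cas10.gene.gene_id:
                    if _anchor_score(other) > _anchor_score(keeper):
                        keeper, other = other, prev
                keeper.cas_span = (
                    min(prev.cas_span[0], loc.cas_span[0]),
                    max(prev.cas_span[1], loc.cas_span[1]),
                )
                current[-1] = keeper
            else:
                current.append(loc)
        merged.extend(current)
    merged.sort(key=lambda l: (l.genome_id, l.contig_id, l.cas_span))
    return merged


def _anchor_score(locus: Locus) -> float:
    return getattr(locus, "_anchor_bitscore", 0.0)


def assign_members(
    loci: Sequence[Locus], genes: Sequence[GeneFeature]
) -> dict[str, list[GeneFeature]]:
    """Assign each gene to at most one locus.

    A gene is a member if its interval overlaps the locus neighborhood by
    >= 1 bp.  A gene overlapping two neighborhoods goes to the locus whose
    cas span is nearest (gap 0 when overlapping the span itself); ties
    break toward the lexicographically smaller locus id.  Genes inside a
    cas span always belong to their own locus.
    """
    members: dict[str, list[GeneFeature]] = {loc.locus_id: [] for loc in loci}
    by_contig: dict[tuple[str, str], list[Locus]] = {}
    for loc in loci:
        by_contig.setdefault((loc.genome_id, loc.contig_id), []).append(loc)
    for g in genes:
        cands = [
            loc
            for loc in by_contig.get((g.genome_id, g.contig_id), ())
            if intervals_overlap(g.interval, loc.neighborhood)
        ]
        if not cands:
            continue
        best = min(
            cands,
            key=lambda loc: (interval_gap(g.interval, loc.cas_span), loc.locus_id),
        )
        members[best.locus_id].append(g)
    for loc in loci:
        members[loc.locus_id].sort(key=lambda g: (g.start, g.end, g.gene_id))
        loc.members = members[loc.locus_id]
    return members


def build_loci(
    genes: Sequence[GeneFeature],
    hits_by_protein: Mapping[str, Sequence[DomainHit]],
    catalogue: FamilyCatalogue,
    contig_lengths: Mapping[str, int],
    genome_id: str,
    evalue_ceiling: float = 1e-4,
    window: int = DEFAULT_WINDOW,
    chain_gap: int = DEFAULT_CHAIN_GAP,
) -> list[Locus]:
    """Full locus assembly for one genome: anchors -> spans -> merge ->
    neighborhoods -> membership.

    Cas10 annotation (cyclase/HD flags) and RN/effector annotation are
    left to the annotator; the returned loci carry placeholder Cas10
    annotations with flags unset.
    """
    anchors = find_cas10_anchors(genes, hits_by_protein, catalogue, evalue_ceiling)
    loci: list[Locus] = []
    for anchor in anchors:
        span = build_cas_span(
            anchor, genes, hits_by_protein, catalogue, chain_gap, evalue_ceiling
        )
        contig_len = contig_lengths.get(anchor.contig_id, span[1] + window)
        loc = Locus(
            locus_id="",  # assigned after merging
            genome_id=genome_id,
            contig_id=anchor.contig_id,
            cas10=Cas10Annotation(gene=anchor, has_cyclase=False, has_hd=False),
            cas_span=span,
            neighborhood=build_neighborhood(span, contig_len, window),
        )
        best = _best_hit(
            list(hits_by_protein.get(anchor.gene_id, ())),
            set(catalogue.cas10_profiles),
            evalue_ceiling,
        )
        loc._anchor_bitscore = best.bitscore if best else 0.0  # type: ignore[attr-defined]
        loci.append(loc)
    loci = merge_overlapping_loci(loci)
    for i, loc in enumerate(loci, start=1):
        loc.locus_id = f"{genome_id}_locus{i:02d}"
        contig_len = contig_lengths.get(loc.contig_id, loc.cas_span[1] + window)
        loc.neighborhood = build_neighborhood(loc.cas_span, contig_len, window)
    assign_members(loci, [g for g in genes])
    return loci


def apply_subtypes(
    loci: Iterable[Locus],
    subtype_rows: Sequence[tuple[str, int, int, str]] = (),
    overrides: Mapping[str, str] | None = None,
) -> None:
    """Attach CRISPR subtypes from a CCTyper-style table and manual overrides.

    ``subtype_rows`` are (contig, start, end, subtype) records matched to a
    locus when the record interval overlaps its cas span.  ``overrides``
    maps locus_id -> subtype and wins over the table.
    """
    for loc in loci:
        for contig, start, end, subtype in subtype_rows:
            if contig == loc.contig_id and intervals_overlap((start, end), loc.cas_span):
                loc.subtype = subtype
                break
        if overrides and loc.locus_id in overrides:
            loc.subtype = overrides[loc.locus_id]


def write_loci_table(loci: Sequence[Locus], path) -> None:
    """TSV: one row per locus with span, neighborhood, subtype and anchor."""
    import csv

    with open(path, "wt", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            [
                "locus_id", "genome_id", "contig_id", "span_start", "span_end",
                "nbh_start", "nbh_end", "subtype", "anchor_gene",
                "has_cyclase", "has_hd", "signals",
            ]
        )
        for loc in loci:
            w.writerow(
                [
                    loc.locus_id, loc.genome_id, loc.contig_id,
                    loc.cas_span[0], loc.cas_span[1],
                    loc.neighborhood[0], loc.neighborhood[1],
                    loc.subtype, loc.cas10.gene.gene_id,
                    int(loc.cas10.has_cyclase), int(loc.cas10.has_hd),
                    ";".join(sorted(loc.signals)),
                ]
            )
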