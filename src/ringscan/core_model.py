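"""Domain types and file I/O shared by every stage of the pipeline.

The pipeline characterizes type III CRISPR-Cas loci: Cas10-anchored cas
operons, the 6 kbp neighborhood around them, and the ring nucleases (RNs)
and cOA-activated effectors encoded there.  This module defines the common
record types (genes, profile hits, annotations, loci) and the readers and
writers for the standard formats the pipeline touches: GFF3 + protein
FASTA for genomes, HMMER per-domain tables ("domtblout") for profile hits,
and GEXF/GraphML for co-occurrence networks.

Coordinate convention: 1-based inclusive base-pair positions throughout
(GFF3 native).  Amino-acid positions in hits are likewise 1-based
inclusive.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import gffutils
import networkx as nx
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: bp interval, 1-based inclusive
Interval = tuple[int, int]


def intervals_overlap(a: Interval, b: Interval) -> bool:
    """True if two 1-based inclusive intervals share >= 1 bp."""
    return a[0] <= b[1] and b[0] <= a[1]


def interval_gap(a: Interval, b: Interval) -> int:
    """Gap in bp between two intervals; 0 if they overlap or abut."""
    if intervals_overlap(a, b):
        return 0
    return max(a[0], b[0]) - min(a[1], b[1]) - 1


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class GeneFeature:
    """One protein-coding gene with contig coordinates and translation."""

    gene_id: str
    genome_id: str
    contig_id: str
    start: int  # 1-based inclusive bp
    end: int  # 1-based inclusive bp
    strand: str  # '+' or '-'
    protein_seq: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if len(self.protein_seq) < 1:
            raise ValueError(f"{self.gene_id}: empty protein sequence")

    @property
    def length_aa(self) -> int:
        return len(self.protein_seq)

    @property
    def interval(self) -> Interval:
        return (self.start, self.end)


@dataclass(frozen=True)
class DomainHit:
    """One profile-vs-protein match from a per-domain HMMER table."""

    protein_id: str
    family_id: str  # raw profile name, not yet mapped to a family
    bitscore: float
    evalue: float
    ali_start: int = 1
    ali_end: int = 1

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"{self.protein_id}: negative e-value")
        if self.ali_start > self.ali_end:
            raise ValueError(f"{self.protein_id}: ali_start > ali_end")


@dataclass(frozen=True)
class FamilyCatalogue:
    """Maps profile names to families and partitions families by role.

    ``profile_to_family`` is total over the configured profile catalogue;
    notably the Csx14 profile maps into the Crn1 ring-nuclease family,
    which subsumes it.
    """

    rn_families: frozenset[str]
    effector_families: frozenset[str]
    cas_core_families: frozenset[str]  # Cas10 plus cas accessory profiles
    cas10_profiles: frozenset[str]
    profile_to_family: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.rn_families & self.effector_families:
            raise ValueError("rn_families and effector_families overlap")

    def family_of(self, profile: str) -> str | None:
        return self.profile_to_family.get(profile)

    def is_rn_profile(self, profile: str) -> bool:
        return self.profile_to_family.get(profile) in self.rn_families

    def is_effector_profile(self, profile: str) -> bool:
        return self.profile_to_family.get(profile) in self.effector_families

    def is_cas10_profile(self, profile: str) -> bool:
        return profile in self.cas10_profiles


RN_FAMILIES = ("Crn1", "Crn2", "Crn3", "Csx15", "Csx16", "Csx20")

EFFECTOR_FAMILIES = (
    "Csx1",
    "Csm6",
    "Csm6-2",
    "Can1",
    "Can2",
    "Cami1",
    "Cam1",
    "CalpL",
    "NucC",
    "Csx23",
    "TIR-SAVED",
    "CorA",
)

CAS_ACCESSORY = ("Cas5", "Cas6", "Cas7", "Cas11")


def default_catalogue(
    extra_effectors: Iterable[str] = (),
) -> FamilyCatalogue:
    """Catalogue with the six RN families (Csx14 folded into Crn1), the
    standard cOA effector panel and the cas-core profiles."""
    effectors = tuple(EFFECTOR_FAMILIES) + tuple(extra_effectors)
    mapping: dict[str, str] = {f: f for f in RN_FAMILIES}
    mapping["Csx14"] = "Crn1"  # Csx14 is a Crn1-family member
    mapping.update({f: f for f in effectors})
    mapping.update({f: f for f in ("Cas10",) + CAS_ACCESSORY})
    return FamilyCatalogue(
        rn_families=frozenset(RN_FAMILIES),
        effector_families=frozenset(effectors),
        cas_core_families=frozenset(("Cas10",) + CAS_ACCESSORY),
        cas10_profiles=frozenset({"Cas10"}),
        profile_to_family=mapping,
    )


SIGNALS = ("cA3", "cA4", "cA6", "SAM-AMP", "unknown")

#: Default effector-family -> second-messenger table.  cA4 assignments for
#: Csx1/Can1/Can2/Cami1/Cam1/CalpL are well established; Csx23, NucC and
#: TIR-SAVED follow companion characterizations and are provisional.
DEFAULT_SIGNAL_MAPPING: dict[str, str] = {
    "Csx1": "cA4",
    "Can1": "cA4",
    "Can2": "cA4",
    "Cami1": "cA4",
    "Cam1": "cA4",
    "CalpL": "cA4",
    "Csx23": "cA4",  # provisional
    "Csm6": "cA6",
    "Csm6-2": "cA6",
    "NucC": "cA3",  # provisional
    "TIR-SAVED": "cA3",  # provisional
    "CorA": "SAM-AMP",  # Cas10-fused CorA-class membrane effector
}


class SignalMapping(dict):
    """Effector family -> signal molecule; unmapped families yield
    ``unknown`` with a warning rather than an error."""

    def signal_for(self, family: str) -> str:
        try:
            return self[family]
        except KeyError:
            logger.warning(
                "effector family %s has no signal mapping; using 'unknown'",
                family,
            )
            return "unknown"


def default_signal_mapping() -> SignalMapping:
    return SignalMapping(DEFAULT_SIGNAL_MAPPING)


@dataclass(frozen=True)
class Cas10Annotation:
    """Cas10 anchor gene with cyclase (GGDD-type) and HD-nuclease flags."""

    gene: GeneFeature
    has_cyclase: bool
    has_hd: bool


@dataclass(frozen=True)
class RNAnnotation:
    """A ring-nuclease call on one gene.

    ``screen_status`` records the conserved-residue screen: candidates
    missing an absolutely conserved residue are kept with status ``fail``
    for audit but excluded from downstream statistics.
    """

    family: str
    gene: GeneFeature
    bitscore: float
    evalue: float
    screen_status: str = "not_screened"  # pass | fail | not_screened
    missing_positions: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if self.gene.length_aa > 250:
            raise ValueError(
                f"{self.gene.gene_id}: RN annotation on protein "
                f"{self.gene.length_aa} aa > 250 aa cutoff"
            )
        if self.screen_status not in ("pass", "fail", "not_screened"):
            raise ValueError(f"bad screen_status {self.screen_status!r}")
        if self.screen_status == "fail" and not self.missing_positions:
            raise ValueError("screen failure must list missing positions")


@dataclass(frozen=True)
class EffectorAnnotation:
    """A cOA-activated effector call on one gene."""

    family: str
    gene: GeneFeature
    bitscore: float
    evalue: float
    signal: str = "unknown"


@dataclass
class Locus:
    """One Cas10-anchored type III CRISPR-Cas locus.

    ``cas_span`` covers the chained cas operon; ``neighborhood`` extends it
    by up to the search window (6 kbp by default) on each side, clipped at
    contig ends.  ``members`` are all genes overlapping the neighborhood.
    """

    locus_id: str
    genome_id: str
    contig_id: str
    cas10: Cas10Annotation
    cas_span: Interval
    neighborhood: Interval
    subtype: str = "unknown"
    members: list[GeneFeature] = field(default_factory=list)
    effectors: list[EffectorAnnotation] = field(default_factory=list)
    rns: list[RNAnnotation] = field(default_factory=list)
    signals: set[str] = field(default_factory=set)

    def passing_rns(self) -> list[RNAnnotation]:
        """RN annotations surviving the conserved-residue screen."""
        return [r for r in self.rns if r.screen_status != "fail"]

    def rn_families_present(self) -> set[str]:
        return {r.family for r in self.passing_rns()}

    def effector_families_present(self) -> set[str]:
        return {e.family for e in self.effectors}


# ---------------------------------------------------------------------------
# GFF3 + protein FASTA


@dataclass(frozen=True)
class ParseIssue:
    line: int  # 1-based line number in the source, 0 if unknown
    message: str


@dataclass
class GenomeAnnotation:
    """Parsed annotation of one genome: genes plus contig lengths."""

    genome_id: str
    contig_lengths: dict[str, int]
    genes: list[GeneFeature]
    issues: list[ParseIssue] = field(default_factory=list)

    def genes_by_contig(self) -> dict[str, list[GeneFeature]]:
        out: dict[str, list[GeneFeature]] = {}
        for g in self.genes:
            out.setdefault(g.contig_id, []).append(g)
        for gs in out.values():
            gs.sort(key=lambda g: (g.start, g.end, g.gene_id))
        return out


def _read_text(source: str | os.PathLike | TextIO) -> str:
    if hasattr(source, "read"):
        return source.read()  # type: ignore[union-attr]
    with open(source, "rt", encoding="utf-8") as fh:
        return fh.read()


def read_protein_fasta(source: str | os.PathLike | TextIO) -> dict[str, str]:
    """Protein FASTA -> {record id: sequence}."""
    handle = source if hasattr(source, "read") else open(source, "rt")
    try:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(handle, "fasta")}
    finally:
        if handle is not source:
            handle.close()


def write_protein_fasta(
    sequences: Mapping[str, str], path: str | os.PathLike
) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, os.fspath(path), "fasta")


def parse_gff(
    source: str | os.PathLike | TextIO,
    proteins: Mapping[str, str],
    genome_id: str = "",
) -> GenomeAnnotation:
    """Parse GFF3 CDS features into :class:`GeneFeature` records.

    Protein sequences are looked up in ``proteins`` by the feature's ID (or
    ``locus_tag``) attribute; features without a resolvable sequence are
    reported in ``issues`` and dropped, as are records with malformed
    coordinates (start > end) or an unknown strand symbol.  Contig lengths
    are taken from ``##sequence-region`` pragmas when present, otherwise
    from the maximum feature end per contig.
    """
    text = _read_text(source)
    issues: list[ParseIssue] = []
    contig_lengths: dict[str, int] = {}

    # pre-scan: validate records and record line provenance; gffutils does
    # not keep line numbers.
    clean_lines: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if stripped.startswith("##sequence-region"):
            parts = stripped.split()
            if len(parts) >= 4:
                contig_lengths[parts[1]] = int(parts[3])
            clean_lines.append(line)
            continue
        if not stripped or stripped.startswith("#"):
            clean_lines.append(line)
            continue
        cols = line.split("\t")
        if len(cols) < 9:
            issues.append(ParseIssue(lineno, f"expected 9 columns, got {len(cols)}"))
            continue
        if cols[2] != "CDS":
            clean_lines.append(line)
            continue
        try:
            start, end = int(cols[3]), int(cols[4])
        except ValueError:
            issues.append(ParseIssue(lineno, f"non-numeric coordinates {cols[3]}..{cols[4]}"))
            continue
        if start > end:
            issues.append(ParseIssue(lineno, f"malformed coordinates: start {start} > end {end}"))
            continue
        if cols[6] not in ("+", "-"):
            issues.append(ParseIssue(lineno, f"unknown strand symbol {cols[6]!r}"))
            continue
        clean_lines.append(line)

    has_data = any(
        l.strip() and not l.lstrip().startswith("#") for l in clean_lines
    )
    genes: list[GeneFeature] = []
    seen_ids: set[str] = set()
    db = (
        gffutils.create_db(
            "\n".join(clean_lines) + "\n",
            ":memory:",
            from_string=True,
            merge_strategy="create_unique",
            keep_order=True,
        )
        if has_data
        else None
    )
    for feat in db.features_of_type("CDS") if db is not None else ():
        gene_id = feat.attributes.get("ID", [None])[0] or feat.attributes.get(
            "locus_tag", [None]
        )[0]
        if gene_id is None:
            issues.append(ParseIssue(0, f"CDS at {feat.seqid}:{feat.start} lacks ID/locus_tag"))
            continue
        if gene_id in seen_ids:
            issues.append(ParseIssue(0, f"duplicate gene id {gene_id}"))
            continue
        seq = proteins.get(gene_id)
        if not seq:
            issues.append(ParseIssue(0, f"no protein sequence for {gene_id}; dropped"))
            continue
        seen_ids.add(gene_id)
        genes.append(
            GeneFeature(
                gene_id=gene_id,
                genome_id=genome_id,
                contig_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                protein_seq=seq,
            )
        )
    for g in genes:
        if g.contig_id not in contig_lengths:
            contig_lengths[g.contig_id] = 0
        contig_lengths[g.contig_id] = max(contig_lengths[g.contig_id], g.end)
    genes.sort(key=lambda g: (g.contig_id, g.start, g.end, g.gene_id))
    return GenomeAnnotation(
        genome_id=genome_id,
        contig_lengths=contig_lengths,
        genes=genes,
        issues=issues,
    )


def write_gff(annotation: GenomeAnnotation, path: str | os.PathLike) -> None:
    """Write CDS features (plus sequence-region pragmas) as GFF3."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for contig in sorted(annotation.contig_lengths):
            fh.write(
                f"##sequence-region {contig} 1 {annotation.contig_lengths[contig]}\n"
            )
        for g in sorted(
            annotation.genes, key=lambda g: (g.contig_id, g.start, g.gene_id)
        ):
            fh.write(
                "\t".join(
                    (
                        g.contig_id,
                        "ringscan",
                        "CDS",
                        str(g.start),
                        str(g.end),
                        ".",
                        g.strand,
                        "0",
                        f"ID={g.gene_id}",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# HMMER per-domain table (domtblout)

_DOMTBL_HEADER = (
    "#{:<29} {:<10} {:>5} {:<20} {:>10} {:>5} {:>9} {:>6} {:>5} {:>3} {:>3} "
    "{:>9} {:>9} {:>6} {:>5} {:>5} {:>5} {:>5} {:>5} {:>5} {:>5} {:>4} {}"
)


def parse_domtbl(
    source: str | os.PathLike | TextIO, strict: bool = True
) -> list[DomainHit]:
    """Parse a HMMER per-domain table ("domtblout") into hits.

    Lines beginning with ``#`` are comments.  The sequence id is column 1
    (target) and the profile name column 4 (query), the hmmsearch layout;
    the independent e-value (column 13), per-domain bit score (column 14)
    and ali coordinates (columns 18-19) are kept.  A non-numeric score or
    e-value raises :class:`ValueError` naming the line, or skips the row
    with a warning when ``strict`` is false.
    """
    text = _read_text(source)
    hits: list[DomainHit] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split(None, 22)
        if len(cols) < 19:
            msg = f"domtbl line {lineno}: expected >= 19 columns, got {len(cols)}"
            if strict:
                raise ValueError(msg)
            logger.warning(msg)
            continue
        try:
            hit = DomainHit(
                protein_id=cols[0],
                family_id=cols[3],
                evalue=float(cols[12]),
                bitscore=float(cols[13]),
                ali_start=int(cols[17]),
                ali_end=int(cols[18]),
            )
        except ValueError as exc:
            msg = f"domtbl line {lineno}: {exc}"
            if strict:
                raise ValueError(msg) from None
            logger.warning(msg)
            continue
        hits.append(hit)
    return hits


def write_domtbl(hits: Sequence[DomainHit], path: str | os.PathLike) -> None:
    """Write hits in the per-domain tabular dialect ``parse_domtbl`` reads."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("# target name        accession   tlen query name           "
                 "accession   qlen   E-value  score  bias   #  of  c-Evalue  "
                 "i-Evalue  score  bias  from    to  from    to  from    to  "
                 "acc description of target\n")
        fh.write("#" + "-" * 120 + "\n")
        for h in hits:
            fh.write(
                f"{h.protein_id:<20} -  0 {h.family_id:<12} - 0 "
                f"{h.evalue:10.3g} {h.bitscore:7.1f} 0.0 1 1 "
                f"{h.evalue:10.3g} {h.evalue:10.3g} {h.bitscore:7.1f} 0.0 "
                f"1 1 {h.ali_start} {h.ali_end} 1 1 0.99 -\n"
            )


def hits_by_protein(hits: Iterable[DomainHit]) -> dict[str, list[DomainHit]]:
    out: dict[str, list[DomainHit]] = {}
    for h in hits:
        out.setdefault(h.protein_id, []).append(h)
    return out


# ---------------------------------------------------------------------------
# network export


def write_gexf(network, path: str | os.PathLike, fmt: str = "gexf") -> None:
    """Export a bipartite RN-effector network as GEXF (or GraphML).

    Nodes carry ``kind`` (RN/effector) and ``signal`` attributes; edges
    carry integer co-occurrence weights.  An edge referencing a missing
    node, or joining two nodes of the same kind, aborts.
    """
    node_kind = {n.node_id: n.kind for n in network.nodes}
    g = nx.Graph()
    for n in network.nodes:
        g.add_node(n.node_id, kind=n.kind, signal=n.signal)
    for e in network.edges:
        for endpoint in (e.rn, e.effector):
            if endpoint not in node_kind:
                raise ValueError(
                    f"edge ({e.rn}, {e.effector}) references missing node "
                    f"{endpoint!r}"
                )
        if node_kind[e.rn] == node_kind[e.effector]:
            raise ValueError(
                f"edge ({e.rn}, {e.effector}) joins two {node_kind[e.rn]} "
                "nodes; network must be bipartite"
            )
        g.add_edge(e.rn, e.effector, weight=int(e.weight))
    if fmt == "gexf":
        nx.write_gexf(g, os.fspath(path))
    elif fmt == "graphml":
        nx.write_graphml(g, os.fspath(path))
    else:
        raise ValueError(f"unknown network format {fmt!r}")
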