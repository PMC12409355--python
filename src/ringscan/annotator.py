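"""Ring-nuclease and effector annotation of locus members.

Ring nucleases (RNs) are small cOA-degrading enzymes; CARF-domain
effectors can hit the same profiles, so RN calls are restricted to
proteins of at most 250 amino acids and then screened for the absolutely
conserved residues of their family, derived from a reference multiple
sequence alignment.  Effector calls take the best effector-profile hit
per gene; a gene never carries both annotations.  Cas10 anchors are
flagged for cyclase (GGDD-type) and HD-nuclease motifs, and the locus
signal molecule set is inferred from the effector families present.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import AlignIO
from biotite.sequence import ProteinSequence
from biotite.sequence.align import SubstitutionMatrix, align_optimal

from .core_model import (
    Cas10Annotation,
    DomainHit,
    EffectorAnnotation,
    FamilyCatalogue,
    GeneFeature,
    Locus,
    RNAnnotation,
    SignalMapping,
)

RN_MAX_LENGTH_AA = 250  # cross-annotation cutoff against CARF effectors

#: Cyclase tetrad variants accepted in the Cas10 Palm domain.
DEFAULT_CYCLASE_PATTERNS = ("GGDD", "GGDE", "SGDD")
#: HD nuclease: His followed by Asp within 4 residues, N-terminal third.
DEFAULT_HD_PATTERN = r"H.{0,3}D"

_BLOSUM62 = SubstitutionMatrix.std_protein_matrix()
_VALID_AA = set("ACDEFGHIKLMNPQRSTVWYBZX*")


@dataclass(frozen=True)
class ConservationProfile:
    """A reference alignment reduced to consensus + conserved columns.

    Columns with gap fraction <= ``g_max`` are *retained*; the consensus
    string covers retained columns only, and ``conserved_columns`` maps
    0-based consensus positions to the residue that is absolutely (or, if
    ``t_cons`` < 1, near-absolutely) conserved there.
    """

    family: str
    consensus: str
    conserved_columns: tuple[tuple[int, str], ...]
    n_sequences: int
    t_cons: float = 1.0
    g_max: float = 0.2

    @property
    def conserved_map(self) -> dict[int, str]:
        return dict(self.conserved_columns)


def build_conservation_profile(
    msa: Sequence[tuple[str, str]] | "AlignIO.MultipleSeqAlignment",
    family: str = "",
    t_cons: float = 1.0,
    g_max: float = 0.2,
) -> ConservationProfile:
    """Reduce an alignment to consensus and conserved columns.

    A column is conserved when its gap fraction is <= ``g_max`` and the
    modal residue reaches frequency >= ``t_cons`` among non-gap rows
    (``t_cons`` = 1.0 means absolutely conserved).  Ragged alignments
    abort.
    """
    if hasattr(msa, "__iter__") and not isinstance(msa, (list, tuple)):
        rows = [(rec.id, str(rec.seq)) for rec in msa]
    else:
        rows = [(rid, str(seq)) for rid, seq in msa]
    if len(rows) < 2:
        raise ValueError("alignment needs >= 2 sequences")
    length = len(rows[0][1])
    for rid, seq in rows:
        if len(seq) != length:
            raise ValueError(
                f"ragged alignment: {rid} has length {len(seq)} != {length}"
            )
    n = len(rows)
    consensus: list[str] = []
    conserved: list[tuple[int, str]] = []
    for col in range(length):
        residues = [seq[col] for _, seq in rows]
        non_gap = [r for r in residues if r not in "-."]
        gap_frac = 1.0 - len(non_gap) / n
        if gap_frac > g_max:
            continue  # column dropped from the consensus
        counts: dict[str, int] = {}
        for r in non_gap:
            counts[r] = counts.get(r, 0) + 1
        modal = max(sorted(counts), key=lambda r: counts[r])
        consensus_idx = len(consensus)
        consensus.append(modal)
        if counts[modal] / len(non_gap) >= t_cons:
            conserved.append((consensus_idx, modal))
    return ConservationProfile(
        family=family,
        consensus="".join(consensus),
        conserved_columns=tuple(conserved),
        n_sequences=n,
        t_cons=t_cons,
        g_max=g_max,
    )


def load_reference_msas(
    directory: str | os.PathLike,
    t_cons: float = 1.0,
    g_max: float = 0.2,
) -> dict[str, ConservationProfile]:
    """Load ``<family>.afa`` reference alignments from a directory."""
    profiles: dict[str, ConservationProfile] = {}
    for name in sorted(os.listdir(directory)):
        if not name.endswith(".afa"):
            continue
        family = name[: -len(".afa")]
        aln = AlignIO.read(os.path.join(directory, name), "fasta")
        profiles[family] = build_conservation_profile(
            aln, family=family, t_cons=t_cons, g_max=g_max
        )
    return profiles


def _as_protein(seq: str) -> ProteinSequence:
    cleaned = "".join(c if c in _VALID_AA else "X" for c in seq.upper())
    return ProteinSequence(cleaned)


def align_to_consensus(candidate: str, consensus: str) -> np.ndarray:
    """Global affine-gap alignment trace of candidate vs consensus.

    BLOSUM62 scoring with gap open 10 / extend 1, terminal gaps
    penalized (true global alignment).  Returns the biotite trace array:
    one row per alignment column, columns (candidate index, consensus
    index), -1 marking a gap.
    """
    ali = align_optimal(
        _as_protein(candidate),
        _as_protein(consensus),
        _BLOSUM62,
        gap_penalty=(-10, -1),
        terminal_penalty=True,
    )[0]
    return ali.trace


def screen_candidate(
    protein_seq: str, profile: ConservationProfile
) -> tuple[str, tuple[tuple[int, str], ...]]:
    """Check a candidate for its family's absolutely conserved residues.

    The candidate is globally aligned to the profile consensus and each
    conserved column is mapped through the alignment.  Status is ``pass``
    iff the candidate carries the expected residue at every conserved
    column; otherwise ``fail`` with the mismatched or deleted positions
    (0-based consensus column, expected residue).
    """
    if not protein_seq:
        raise ValueError("empty protein sequence")
    if not profile.conserved_columns:
        raise ValueError(
            f"profile {profile.family or '<unnamed>'} has no conserved "
            "columns; unusable for screening"
        )
    trace = align_to_consensus(protein_seq, profile.consensus)
    cons_to_cand: dict[int, int] = {
        int(c): int(p) for p, c in trace if c >= 0
    }
    missing: list[tuple[int, str]] = []
    for col, expected in profile.conserved_columns:
        cand_idx = cons_to_cand.get(col, -1)
        if cand_idx < 0 or protein_seq[cand_idx].upper() != expected:
            missing.append((col, expected))
    if missing:
        return "fail", tuple(missing)
    return "pass", ()


def classify_rn(
    gene: GeneFeature,
    hits: Sequence[DomainHit],
    catalogue: FamilyCatalogue,
    evalue_ceiling: float = 1e-4,
) -> RNAnnotation | None:
    """Call a ring-nuclease family on one gene, or ``None``.

    Requires an RN-profile hit at or below the e-value ceiling and a
    protein of at most 250 aa.  The highest-bit-score hit wins; ties
    break by smaller e-value, then alphabetical family.  Profile names
    are mapped through the catalogue (Csx14 -> Crn1).  The returned
    annotation is not yet screened for conserved residues.
    """
    if gene.length_aa > RN_MAX_LENGTH_AA:
        return None
    cands = [
        h
        for h in hits
        if catalogue.is_rn_profile(h.family_id) and h.evalue <= evalue_ceiling
    ]
    if not cands:
        return None
    best = min(
        cands,
        key=lambda h: (-h.bitscore, h.evalue, catalogue.family_of(h.family_id)),
    )
    return RNAnnotation(
        family=catalogue.family_of(best.family_id),  # type: ignore[arg-type]
        gene=gene,
        bitscore=best.bitscore,
        evalue=best.evalue,
    )


def _best_effector_hit(
    hits: Sequence[DomainHit],
    catalogue: FamilyCatalogue,
    evalue_ceiling: float,
) -> DomainHit | None:
    cands = [
        h
        for h in hits
        if catalogue.is_effector_profile(h.family_id) and h.evalue <= evalue_ceiling
    ]
    if not cands:
        return None
    return min(cands, key=lambda h: (-h.bitscore, h.evalue, h.family_id))


def resolve_gene_roles(
    gene: GeneFeature,
    hits: Sequence[DomainHit],
    catalogue: FamilyCatalogue,
    evalue_ceiling: float = 1e-4,
    signal_mapping: SignalMapping | None = None,
) -> tuple[EffectorAnnotation | None, RNAnnotation | None]:
    """Apply the cross-annotation rule; at most one of the two is set.

    CARF-domain effectors often hit RN profiles too.  When a gene
    qualifies for both roles: the effector call wins for proteins longer
    than 250 aa; the RN call wins at <= 250 aa only when its bit score
    beats the effector's; otherwise the effector wins.
    """
    eff_hit = _best_effector_hit(hits, catalogue, evalue_ceiling)
    rn = classify_rn(gene, hits, catalogue, evalue_ceiling)
    if eff_hit is not None and rn is not None:
        if gene.length_aa <= RN_MAX_LENGTH_AA and rn.bitscore > eff_hit.bitscore:
            return None, rn
        rn = None
    if eff_hit is not None:
        family = catalogue.family_of(eff_hit.family_id)
        signal = (
            signal_mapping.signal_for(family) if signal_mapping else "unknown"
        )
        return (
            EffectorAnnotation(
                family=family,  # type: ignore[arg-type]
                gene=gene,
                bitscore=eff_hit.bitscore,
                evalue=eff_hit.evalue,
                signal=signal,
            ),
            None,
        )
    return None, rn


def annotate_effectors(
    locus_members: Sequence[GeneFeature],
    hits_by_protein: Mapping[str, Sequence[DomainHit]],
    catalogue: FamilyCatalogue,
    evalue_ceiling: float = 1e-4,
    signal_mapping: SignalMapping | None = None,
) -> list[EffectorAnnotation]:
    """Best effector-family hit per member gene, after cross-annotation
    resolution against the RN call."""
    out = []
    for g in locus_members:
        eff, _ = resolve_gene_roles(
            g, hits_by_protein.get(g.gene_id, ()), catalogue, evalue_ceiling,
            signal_mapping,
        )
        if eff is not None:
            out.append(eff)
    return out


def annotate_cas10(
    gene: GeneFeature,
    cyclase_patterns: Sequence[str] = DEFAULT_CYCLASE_PATTERNS,
    hd_pattern: str = DEFAULT_HD_PATTERN,
) -> Cas10Annotation:
    """Flag cyclase and HD-nuclease motifs on a Cas10 protein.

    The cyclase call is the presence of any configured tetrad motif
    (GGDD/GGDE/SGDD by default) anywhere in the sequence; the HD call is
    the presence of an H...D motif (Asp within 4 residues of a His) in
    the N-terminal third, where the HD domain sits in Cas10.
    """
    seq = gene.protein_seq.upper()
    has_cyclase = any(re.search(p, seq) for p in cyclase_patterns)
    n_third = seq[: max(1, len(seq) // 3)]
    has_hd = re.search(hd_pattern, n_third) is not None
    return Cas10Annotation(gene=gene, has_cyclase=has_cyclase, has_hd=has_hd)


def infer_signals(
    effectors: Iterable[EffectorAnnotation], mapping: SignalMapping
) -> set[str]:
    """Union of signal molecules implied by the effector families present;
    empty when the locus has no effector."""
    return {mapping.signal_for(e.family) for e in effectors}


def annotate_locus(
    locus: Locus,
    hits_by_protein: Mapping[str, Sequence[DomainHit]],
    catalogue: FamilyCatalogue,
    profiles: Mapping[str, ConservationProfile],
    evalue_ceiling: float = 1e-4,
    signal_mapping: SignalMapping | None = None,
    cyclase_patterns: Sequence[str] = DEFAULT_CYCLASE_PATTERNS,
    hd_pattern: str = DEFAULT_HD_PATTERN,
) -> Locus:
    """Annotate one assembled locus in place: effectors, screened RNs,
    Cas10 motif flags and inferred signals."""
    mapping = signal_mapping or SignalMapping()
    effectors: list[EffectorAnnotation] = []
    rns: list[RNAnnotation] = []
    for g in locus.members:
        eff, rn = resolve_gene_roles(
            g, hits_by_protein.get(g.gene_id, ()), catalogue, evalue_ceiling,
            mapping,
        )
        if eff is not None:
            effectors.append(eff)
        if rn is not None:
            rns.append(screen_rn(rn, profiles))
    locus.effectors = effectors
    locus.rns = rns
    locus.cas10 = annotate_cas10(
        locus.cas10.gene, cyclase_patterns, hd_pattern
    )
    locus.signals = infer_signals(effectors, mapping)
    return locus


def screen_rn(
    rn: RNAnnotation, profiles: Mapping[str, ConservationProfile]
) -> RNAnnotation:
    """Run the conserved-residue screen for the annotation's family.

    Families without a reference profile stay ``not_screened``.
    """
    profile = profiles.get(rn.family)
    if profile is None or not profile.conserved_columns:
        return rn
    status, missing = screen_candidate(rn.gene.protein_seq, profile)
    return RNAnnotation(
        family=rn.family,
        gene=rn.gene,
        bitscore=rn.bitscore,
        evalue=rn.evalue,
        screen_status=status,
        missing_positions=missing,
    )


def screen_genome_rns(
    genes: Sequence[GeneFeature],
    hits_by_protein: Mapping[str, Sequence[DomainHit]],
    catalogue: FamilyCatalogue,
    profiles: Mapping[str, ConservationProfile],
    evalue_ceiling: float = 1e-4,
) -> list[RNAnnotation]:
    """Genome-wide RN scan with no locus restriction.

    Same length cutoff and conserved-residue screen as the locus path;
    used for background-frequency estimates (RNs in genomes without a
    type III locus) and for phage proteome scans.
    """
    out = []
    for g in genes:
        rn = classify_rn(g, hits_by_protein.get(g.gene_id, ()), catalogue, evalue_ceiling)
        if rn is not None:
            out.append(screen_rn(rn, profiles))
    return out
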