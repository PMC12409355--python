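"""Synthetic genomes, proteomes, hit tables and phage sets with planted
ground truth.

The generator emulates the statistical structure of a large prokaryotic
survey at desk scale: multi-gene type III CRISPR-Cas loci anchored on
Cas10 (with or without an intact cyclase motif), cOA effector genes and
ring-nuclease (RN) genes in the 6 kbp neighborhood, plus the failure
modes the pipeline's filters exist for — long CARF-domain effectors that
also hit RN profiles, RN-like proteins missing an absolutely conserved
residue, RN genes beyond the 6 kbp window, RN genes in genomes with no
locus, and spurious weak profile hits.  Every planted gene carries an
expected pipeline verdict in a truth table, so downstream stages are
testable row by row.

Default frequencies follow the field's reported landscape: Csx20 and
Csx16 are the most common RN families and Crn2 the rarest in cellular
genomes, RN presence is conditioned on the effector family (high for
Cam1 and Can1/Can2, low for Cami1 whose sensor domain has intrinsic RN
activity, zero for non-cA4 effectors), about 4% of RN-positive loci
carry two RNs, about a quarter of Csx15-carrying genomes lack a type III
locus, and phage-encoded RNs are dominated by Crn2/AcrIII-1.

Sequences are not evolved; proteins are random strings except where a
planted family identity matters, in which case they derive from the
family's synthetic reference alignment so that the conserved-residue
screen has real signal to find.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core_model import (
    AA_ALPHABET,
    DomainHit,
    GeneFeature,
    GenomeAnnotation,
    write_domtbl,
    write_gff,
    write_protein_fasta,
)

RN_FAMILY_WEIGHTS = {
    "Csx20": 78.0,
    "Csx16": 68.0,
    "Crn1": 44.0,
    "Crn3": 37.0,
    "Csx15": 18.0,
    "Crn2": 7.0,
}

EFFECTOR_WEIGHTS = {
    "Csx1": 0.35,
    "Csm6": 0.15,
    "Csm6-2": 0.05,
    "Can1": 0.08,
    "Can2": 0.07,
    "Cami1": 0.08,
    "Cam1": 0.08,
    "CalpL": 0.04,
    "NucC": 0.04,
    "Csx23": 0.03,
    "TIR-SAVED": 0.03,
}

#: P(locus has >= 1 RN | its primary effector family).  cA4-activated
#: effectors only; Cami1 is low because its sensor degrades its own
#: activator, Cam1 high because it cannot.
RN_GIVEN_EFFECTOR = {
    "Csx1": 0.34,
    "Can1": 0.66,
    "Can2": 0.66,
    "Cami1": 0.30,
    "Cam1": 0.81,
    "CalpL": 0.39,
    "Csx23": 0.39,
}

SUBTYPE_WEIGHTS = {
    "III-A": 0.40,
    "III-B": 0.35,
    "III-D": 0.15,
    "III-C": 0.05,
    "III-F": 0.05,
}

PHAGE_RN_WEIGHTS = {"Crn2": 36.0, "Csx20": 4.0, "Csx16": 2.0}

CAS_ACCESSORY_PROFILES = ("Cas5", "Cas6", "Cas7", "Cas11")

VERDICT_ANNOTATED = "annotated"
VERDICT_LENGTH = "rejected-by-length"
VERDICT_SCREEN = "rejected-by-screen"
VERDICT_WINDOW = "rejected-by-window"
VERDICT_BACKGROUND = "background"

TRUTH_COLUMNS = (
    "gene_id",
    "genome_id",
    "locus_id",
    "role",
    "family",
    "expected_verdict",
)


@dataclass
class SimConfig:
    """Parameters of the synthetic survey.

    Probabilities are per locus unless noted; decoys are absolute counts
    distributed over eligible loci/genomes so that filter behaviour can
    be verified exactly.  ``n_orphan_rns='auto'`` plants just enough
    orphan Csx15 genes (in genomes without any locus) to put the Csx15
    no-locus background fraction at ``orphan_background_frac``.
    """

    n_genomes: int = 100
    contig_length: int = 120_000
    #: P(genome carries 0, 1, 2, 3 loci)
    loci_per_genome_weights: tuple[float, ...] = (0.30, 0.50, 0.15, 0.05)
    effector_weights: dict[str, float] = field(
        default_factory=lambda: dict(EFFECTOR_WEIGHTS)
    )
    rn_weights: dict[str, float] = field(
        default_factory=lambda: dict(RN_FAMILY_WEIGHTS)
    )
    rn_given_effector: dict[str, float] = field(
        default_factory=lambda: dict(RN_GIVEN_EFFECTOR)
    )
    default_rn_given_effector: float = 0.0
    p_no_effector_locus: float = 0.13
    p_second_effector: float = 0.15
    p_rn_no_effector: float = 0.33
    p_multi_rn: float = 0.014  # unconditional P(locus carries 2 RNs)
    p_cyclase_negative: float = 0.08
    p_hd: float = 0.20
    subtype_weights: dict[str, float] = field(
        default_factory=lambda: dict(SUBTYPE_WEIGHTS)
    )
    # planted failure modes (absolute counts)
    n_long_carf_decoys: int = 0
    n_missing_residue_decoys: int = 0
    n_out_of_window_rns: int = 0
    n_orphan_rns: int | str = 0  # int or "auto"
    orphan_family: str = "Csx15"
    orphan_background_frac: float = 0.25
    # noise
    spurious_hit_rate: float = 0.0  # P(extra weak hit) per gene
    spurious_evalue_range: tuple[float, float] = (1e-3, 10.0)
    hard_noise: bool = False  # overlap spurious e-values with real ones
    # geometry
    window: int = 6000
    # reference alignments
    msa_n_seqs: int = 20
    msa_n_conserved: int = 6
    # phage set
    n_phage: int = 0
    phage_rn_fraction: float = 0.30
    phage_rn_weights: dict[str, float] = field(
        default_factory=lambda: dict(PHAGE_RN_WEIGHTS)
    )
    n_phage_missing_residue: int = 0
    phage_proteome_size: tuple[int, int] = (15, 40)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "p_no_effector_locus",
            "p_second_effector",
            "p_rn_no_effector",
            "p_multi_rn",
            "p_cyclase_negative",
            "p_hd",
            "spurious_hit_rate",
            "phage_rn_fraction",
            "orphan_background_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("effector_weights", "rn_weights", "phage_rn_weights"):
            w = getattr(self, name)
            if any(x < 0 for x in w.values()) or not any(w.values()):
                raise ValueError(f"{name}: weights must be non-negative, not all zero")
        if abs(sum(self.loci_per_genome_weights) - 1.0) > 1e-9:
            raise ValueError("loci_per_genome_weights must sum to 1")

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SimConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("loci_per_genome_weights", "spurious_evalue_range", "phage_proteome_size"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# synthetic protein families


@dataclass(frozen=True)
class SyntheticFamily:
    """One RN family's generated reference alignment and truth.

    ``conserved_positions`` are 0-based columns of the (gap-free-column)
    consensus that are absolutely conserved by construction; every other
    column is guaranteed polymorphic in the alignment.
    """

    family: str
    consensus: str
    conserved_positions: tuple[int, ...]
    msa: tuple[tuple[str, str], ...]  # (seq id, aligned sequence)


def _rand_protein(rng: np.random.Generator, length: int, alphabet: str = AA_ALPHABET) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def make_families(config: SimConfig) -> dict[str, SyntheticFamily]:
    """Generate one reference MSA per RN family, deterministically from
    the config seed.

    Each family gets ``msa_n_seqs`` aligned sequences with exactly
    ``msa_n_conserved`` absolutely conserved, gap-free columns; every
    non-conserved column is forced to be polymorphic among non-gap rows
    so that the conserved set recovered from the alignment equals the
    planted one.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 17]))
    families: dict[str, SyntheticFamily] = {}
    for fam in sorted(config.rn_weights):
        length = int(rng.integers(110, 171))
        consensus = _rand_protein(rng, length)
        conserved = tuple(
            sorted(rng.choice(length, size=config.msa_n_conserved, replace=False).tolist())
        )
        cons_set = set(conserved)
        n = config.msa_n_seqs
        cols: list[list[str]] = []
        for pos in range(length):
            base = consensus[pos]
            if pos in cons_set:
                cols.append([base] * n)
                continue
            col = [
                base if rng.random() < 0.7 else _rand_protein(rng, 1)
                for _ in range(n)
            ]
            # a few gaps, never enough to drop the column (g_max 0.2)
            if rng.random() < 0.15:
                for i in rng.choice(n, size=int(rng.integers(1, 4)), replace=False):
                    col[i] = "-"
            # force polymorphism among non-gap rows
            non_gap = [i for i, c in enumerate(col) if c != "-"]
            residues = {col[i] for i in non_gap}
            if len(residues) < 2:
                i = int(rng.choice(non_gap))
                other = _rand_protein(rng, 1)
                while other == col[i]:
                    other = _rand_protein(rng, 1)
                col[i] = other
            cols.append(col)
        msa = tuple(
            (f"{fam}_ref{i + 1:02d}", "".join(cols[p][i] for p in range(length)))
            for i in range(n)
        )
        families[fam] = SyntheticFamily(
            family=fam,
            consensus=consensus,
            conserved_positions=conserved,
            msa=msa,
        )
    return families


def _family_variant(
    rng: np.random.Generator, fam: SyntheticFamily, break_conserved: bool = False
) -> str:
    """A family member: the consensus with a few substitutions at
    non-conserved positions; optionally one conserved residue broken."""
    seq = list(fam.consensus)
    free = [i for i in range(len(seq)) if i not in set(fam.conserved_positions)]
    n_mut = int(rng.integers(1, 9))
    for i in rng.choice(free, size=min(n_mut, len(free)), replace=False):
        new = _rand_protein(rng, 1)
        while new == seq[i]:
            new = _rand_protein(rng, 1)
        seq[i] = new
    if break_conserved:
        i = int(rng.choice(fam.conserved_positions))
        new = _rand_protein(rng, 1)
        while new == seq[i]:
            new = _rand_protein(rng, 1)
        seq[i] = new
    return "".join(seq)


_CAS10_ALPHABET = AA_ALPHABET.replace("H", "")  # H inserted only deliberately
_CYCLASE_MOTIFS = ("GGDD", "GGDE", "SGDD")


def _cas10_protein(rng: np.random.Generator, cyclase: bool, hd: bool) -> str:
    length = int(rng.integers(650, 801))
    seq = _rand_protein(rng, length, _CAS10_ALPHABET)
    for motif in _CYCLASE_MOTIFS:  # scrub chance occurrences
        while motif in seq:
            seq = seq.replace(motif, motif[0] + _rand_protein(rng, 1) + motif[2:], 1)
    if cyclase:
        pos = int(rng.integers(length // 2, length - 10))
        seq = seq[:pos] + "GGDD" + seq[pos + 4 :]
    if hd:
        pos = int(rng.integers(5, length // 3 - 6))
        seq = seq[:pos] + "HSD" + seq[pos + 3 :]
    return seq


# ---------------------------------------------------------------------------
# e-value / score models


def _real_evalue(rng: np.random.Generator) -> float:
    return float(10.0 ** rng.uniform(-50, -10))


def _real_score(rng: np.random.Generator) -> float:
    return float(np.round(rng.uniform(60, 300), 1))


def _spurious_hit(
    rng: np.random.Generator, protein_id: str, length_aa: int, config: SimConfig
) -> DomainHit:
    lo, hi = config.spurious_evalue_range
    if config.hard_noise:
        lo = 1e-6  # overlaps the real-hit range: stresses the ceiling
    profile = str(
        rng.choice(
            sorted(config.rn_weights)
            + sorted(config.effector_weights)
            + ["Cas10", *CAS_ACCESSORY_PROFILES]
        )
    )
    ev = float(10.0 ** rng.uniform(np.log10(lo), np.log10(hi)))
    end = int(rng.integers(5, max(6, length_aa)))
    return DomainHit(
        protein_id=protein_id,
        family_id=profile,
        bitscore=float(np.round(rng.uniform(8, 25), 1)),
        evalue=ev,
        ali_start=1,
        ali_end=end,
    )


# ---------------------------------------------------------------------------
# dataset assembly


@dataclass
class SyntheticDataset:
    """In-memory synthetic survey: genomes, hits, references and truth."""

    config: SimConfig
    genomes: dict[str, GenomeAnnotation]
    hits: dict[str, list[DomainHit]]
    families: dict[str, SyntheticFamily]
    truth: pd.DataFrame
    subtype_rows: dict[str, list[tuple[str, int, int, str]]]
    tree_newick: str | None = None

    def write(self, out_dir: str | os.PathLike) -> None:
        """Materialize as GFF3 + protein FASTA per genome, one domtbl per
        genome, reference ``<family>.afa`` alignments, truth and subtype
        TSVs, the config YAML and the Cas10 tree (newick)."""
        out = os.fspath(out_dir)
        for sub in ("genomes", "hits", "msas"):
            os.makedirs(os.path.join(out, sub), exist_ok=True)
        for gid in sorted(self.genomes):
            ann = self.genomes[gid]
            write_gff(ann, os.path.join(out, "genomes", f"{gid}.gff"))
            write_protein_fasta(
                {g.gene_id: g.protein_seq for g in ann.genes},
                os.path.join(out, "genomes", f"{gid}.faa"),
            )
            write_domtbl(
                self.hits.get(gid, []), os.path.join(out, "hits", f"{gid}.domtbl")
            )
        for fam in sorted(self.families):
            with open(os.path.join(out, "msas", f"{fam}.afa"), "wt") as fh:
                for rid, seq in self.families[fam].msa:
                    fh.write(f">{rid}\n{seq}\n")
        self.truth.to_csv(os.path.join(out, "truth.tsv"), sep="\t", index=False)
        rows = [
            {"genome_id": gid, "contig": c, "start": s, "end": e, "subtype": st}
            for gid, lst in sorted(self.subtype_rows.items())
            for c, s, e, st in lst
        ]
        pd.DataFrame(rows, columns=["genome_id", "contig", "start", "end", "subtype"]).to_csv(
            os.path.join(out, "subtypes.tsv"), sep="\t", index=False
        )
        if self.tree_newick:
            with open(os.path.join(out, "cas10_tree.nwk"), "wt") as fh:
                fh.write(self.tree_newick + "\n")
        self.config.to_yaml(os.path.join(out, "config.yaml"))


class _GenomePlacer:
    """Places genes left to right on one contig, tracking the cursor."""

    def __init__(self, genome_id: str, contig_id: str, contig_length: int):
        self.genome_id = genome_id
        self.contig_id = contig_id
        self.contig_length = contig_length
        self.cursor = 1
        self.genes: list[GeneFeature] = []
        self._n = 0

    def place(
        self,
        rng: np.random.Generator,
        protein: str,
        gap: int,
        at: int | None = None,
    ) -> GeneFeature:
        start = at if at is not None else self.cursor + gap
        end = start + 3 * len(protein) - 1
        if end > self.contig_length:
            raise ValueError(
                f"{self.genome_id}: contig too short ({self.contig_length} bp) "
                f"for requested gene ending at {end} bp"
            )
        if self.genes and start <= self.genes[-1].end:
            raise ValueError(
                f"{self.genome_id}: gene placement overlap at {start} bp"
            )
        self._n += 1
        gene = GeneFeature(
            gene_id=f"{self.genome_id}_g{self._n:04d}",
            genome_id=self.genome_id,
            contig_id=self.contig_id,
            start=start,
            end=end,
            strand="+" if rng.random() < 0.8 else "-",
            protein_seq=protein,
        )
        self.genes.append(gene)
        self.cursor = end + 1
        return gene


def _weighted_choice(rng: np.random.Generator, weights: Mapping[str, float]) -> str:
    names = sorted(weights)
    w = np.array([weights[n] for n in names], dtype=float)
    return str(rng.choice(names, p=w / w.sum()))


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate the full synthetic survey for one config.

    Deterministic given ``config.seed``.  Planted RN proteins are <= 250
    aa family variants carrying all conserved residues; long CARF decoys
    are >= 251 aa and hit both an effector and an RN profile;
    missing-residue decoys have one conserved position substituted;
    out-of-window RN genes start more than ``window`` bp past the cas
    span; orphan RNs sit in genomes with no locus.  Spurious hits are
    added per gene at the configured rate with e-values above the real
    range (unless ``hard_noise``).
    """
    families = make_families(config)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 29]))

    genome_ids = [f"G{i:04d}" for i in range(1, config.n_genomes + 1)]
    n_loci_per_genome = {
        gid: int(
            rng.choice(
                len(config.loci_per_genome_weights),
                p=np.array(config.loci_per_genome_weights),
            )
        )
        for gid in genome_ids
    }
    locus_slots = [
        (gid, k)
        for gid in genome_ids
        for k in range(n_loci_per_genome[gid])
    ]
    no_locus_genomes = [g for g in genome_ids if n_loci_per_genome[g] == 0]

    def distribute(n: int, what: str) -> dict[tuple[str, int], int]:
        if n > len(locus_slots):
            raise ValueError(
                f"cannot plant {n} {what}: only {len(locus_slots)} loci available"
            )
        chosen = rng.permutation(len(locus_slots))[:n]
        out: dict[tuple[str, int], int] = {}
        for i in chosen:
            out[locus_slots[int(i)]] = 1
        return out

    carf_slots = distribute(config.n_long_carf_decoys, "long CARF decoys")
    screen_slots = distribute(config.n_missing_residue_decoys, "missing-residue decoys")
    window_slots = distribute(config.n_out_of_window_rns, "out-of-window RNs")

    genomes: dict[str, GenomeAnnotation] = {}
    all_hits: dict[str, list[DomainHit]] = {}
    truth_rows: list[dict] = []
    subtype_rows: dict[str, list[tuple[str, int, int, str]]] = {}
    csx15_carrier_genomes: set[str] = set()
    cas10_ids: list[str] = []

    def real_hit(gene: GeneFeature, profile: str) -> DomainHit:
        return DomainHit(
            protein_id=gene.gene_id,
            family_id=profile,
            bitscore=_real_score(rng),
            evalue=_real_evalue(rng),
            ali_start=1,
            ali_end=gene.length_aa,
        )

    def truth(gene: GeneFeature, locus_id: str, role: str, family: str, verdict: str) -> None:
        truth_rows.append(
            {
                "gene_id": gene.gene_id,
                "genome_id": gene.genome_id,
                "locus_id": locus_id,
                "role": role,
                "family": family,
                "expected_verdict": verdict,
            }
        )

    for gid in genome_ids:
        placer = _GenomePlacer(gid, "ctg1", config.contig_length)
        hits: list[DomainHit] = []
        subtype_rows[gid] = []
        placer.cursor = int(rng.integers(200, 2000))

        for k in range(n_loci_per_genome[gid]):
            locus_id = f"{gid}_L{k + 1}"
            for _ in range(int(rng.integers(0, 3))):  # leading background
                g = placer.place(rng, _rand_protein(rng, int(rng.integers(80, 401))), int(rng.integers(300, 1500)))
                truth(g, "", "background", "", VERDICT_BACKGROUND)

            # upstream in-window decoys (their own 6 kbp budget)
            upstream: list[tuple[str, str, str, str]] = []  # (protein, role, family, verdict) + profiles handled below
            if (gid, k) in carf_slots:
                fam = _weighted_choice(rng, config.rn_weights)
                core = _family_variant(rng, families[fam])
                pad = int(rng.integers(301, 451)) - len(core)
                protein = core + _rand_protein(rng, max(pad, 60))
                g = placer.place(rng, protein, int(rng.integers(150, 400)))
                hits.append(real_hit(g, fam))
                hits.append(real_hit(g, "Csx1"))  # the CARF effector face
                truth(g, locus_id, "decoy:long_carf", fam, VERDICT_LENGTH)
            if (gid, k) in screen_slots:
                fam = _weighted_choice(rng, config.rn_weights)
                g = placer.place(
                    rng, _family_variant(rng, families[fam], break_conserved=True),
                    int(rng.integers(150, 400)),
                )
                hits.append(real_hit(g, fam))
                truth(g, locus_id, "decoy:missing_residue", fam, VERDICT_SCREEN)

            # cas operon: Cas10 then accessory genes, gaps under the chain rule
            subtype = _weighted_choice(rng, config.subtype_weights)
            cyclase_neg = (
                subtype in ("III-C", "III-F") or rng.random() < config.p_cyclase_negative
            )
            cas10 = placer.place(
                rng,
                _cas10_protein(rng, not cyclase_neg, rng.random() < config.p_hd),
                int(rng.integers(150, 400)),
            )
            hits.append(real_hit(cas10, "Cas10"))
            truth(cas10, locus_id, "cas10", "Cas10", VERDICT_ANNOTATED)
            cas10_ids.append(cas10.gene_id)
            span_start = cas10.start
            for _ in range(int(rng.integers(2, 5))):
                prof = str(rng.choice(CAS_ACCESSORY_PROFILES))
                g = placer.place(rng, _rand_protein(rng, int(rng.integers(200, 351))), int(rng.integers(20, 300)))
                hits.append(real_hit(g, prof))
                truth(g, locus_id, "cas_core", prof, VERDICT_ANNOTATED)
            span_end = placer.genes[-1].end
            subtype_rows[gid].append(("ctg1", span_start, span_end, subtype))

            # effectors and RNs downstream, inside the window
            eff_fams: list[str] = []
            if rng.random() >= config.p_no_effector_locus:
                eff_fams.append(_weighted_choice(rng, config.effector_weights))
                if rng.random() < config.p_second_effector:
                    rest = {
                        f: w
                        for f, w in config.effector_weights.items()
                        if f != eff_fams[0] and w > 0
                    }
                    if rest:
                        eff_fams.append(_weighted_choice(rng, rest))
            rn_fams: list[str] = []
            if rng.random() < config.p_multi_rn:
                first = _weighted_choice(rng, config.rn_weights)
                rest = {f: w for f, w in config.rn_weights.items() if f != first and w > 0}
                rn_fams = [first, _weighted_choice(rng, rest)] if rest else [first]
            else:
                p = (
                    config.rn_given_effector.get(
                        eff_fams[0], config.default_rn_given_effector
                    )
                    if eff_fams
                    else config.p_rn_no_effector
                )
                if rng.random() < p:
                    rn_fams = [_weighted_choice(rng, config.rn_weights)]

            accessory: list[tuple[str, str, str]] = []  # (kind, family, protein)
            for fam in rn_fams:
                accessory.append(("rn", fam, _family_variant(rng, families[fam])))
            for fam in eff_fams:
                accessory.append(("effector", fam, _rand_protein(rng, int(rng.integers(300, 501)))))
            rng.shuffle(accessory)
            for kind, fam, protein in accessory:
                g = placer.place(rng, protein, int(rng.integers(150, 400)))
                if g.start > span_end + config.window:
                    raise AssertionError("accessory gene escaped the window")
                if kind == "rn":
                    profile = fam
                    if fam == "Crn1" and rng.random() < 0.3:
                        profile = "Csx14"  # Crn1-family profile under its old name
                    hits.append(real_hit(g, profile))
                    truth(g, locus_id, f"rn:{fam}", fam, VERDICT_ANNOTATED)
                    if fam == config.orphan_family:
                        csx15_carrier_genomes.add(gid)
                else:
                    hits.append(real_hit(g, fam))
                    truth(g, locus_id, f"effector:{fam}", fam, VERDICT_ANNOTATED)

            if (gid, k) in window_slots:
                fam = _weighted_choice(rng, config.rn_weights)
                at = span_end + config.window + 1 + int(rng.integers(600, 2500))
                g = placer.place(rng, _family_variant(rng, families[fam]), 0, at=at)
                hits.append(real_hit(g, fam))
                truth(g, locus_id, "decoy:out_of_window", fam, VERDICT_WINDOW)
                if fam == config.orphan_family:
                    csx15_carrier_genomes.add(gid)

            # spacing: neighborhoods of consecutive loci must stay disjoint
            # and out-of-window genes clear of the next locus's window
            placer.cursor = max(
                span_end + 2 * config.window + 1,
                placer.genes[-1].end + config.window + 501,
            ) + int(rng.integers(0, 1500))

        for _ in range(int(rng.integers(1, 4))):  # trailing background
            g = placer.place(rng, _rand_protein(rng, int(rng.integers(80, 401))), int(rng.integers(300, 1500)))
            truth(g, "", "background", "", VERDICT_BACKGROUND)

        genomes[gid] = GenomeAnnotation(
            genome_id=gid,
            contig_lengths={"ctg1": config.contig_length},
            genes=placer.genes,
        )
        all_hits[gid] = hits

    # orphan RNs: genomes with no locus carrying the orphan family
    n_orphans = config.n_orphan_rns
    if n_orphans == "auto":
        f = config.orphan_background_frac
        n_orphans = int(round(len(csx15_carrier_genomes) * f / (1.0 - f)))
    n_orphans = min(int(n_orphans), len(no_locus_genomes))
    orphan_hosts = [
        no_locus_genomes[int(i)]
        for i in rng.permutation(len(no_locus_genomes))[:n_orphans]
    ]
    for gid in orphan_hosts:
        ann = genomes[gid]
        placer = _GenomePlacer(gid, "ctg1", config.contig_length)
        placer.genes = list(ann.genes)
        placer._n = len(ann.genes)
        placer.cursor = (ann.genes[-1].end + 1) if ann.genes else int(rng.integers(200, 2000))
        fam = config.orphan_family
        g = placer.place(rng, _family_variant(rng, families[fam]), int(rng.integers(500, 2000)))
        all_hits[gid].append(
            DomainHit(
                protein_id=g.gene_id,
                family_id=fam,
                bitscore=_real_score(rng),
                evalue=_real_evalue(rng),
                ali_start=1,
                ali_end=g.length_aa,
            )
        )
        truth(g, "", "decoy:orphan_rn", fam, VERDICT_WINDOW)
        ann.genes = placer.genes

    # spurious weak hits
    if config.spurious_hit_rate > 0:
        for gid in genome_ids:
            for g in genomes[gid].genes:
                if rng.random() < config.spurious_hit_rate:
                    all_hits[gid].append(
                        _spurious_hit(rng, g.gene_id, g.length_aa, config)
                    )

    truth_df = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    tree = _random_tree(rng, cas10_ids) if len(cas10_ids) >= 2 else None
    return SyntheticDataset(
        config=config,
        genomes=genomes,
        hits=all_hits,
        families=families,
        truth=truth_df,
        subtype_rows=subtype_rows,
        tree_newick=tree,
    )


def _random_tree(rng: np.random.Generator, leaves: Sequence[str]) -> str:
    """Random binary newick over the given leaf labels."""
    nodes = [f"{l}:{rng.uniform(0.01, 0.5):.4f}" for l in leaves]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{rng.uniform(0.01, 0.5):.4f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0].rsplit(":", 1)[0] + ";"


# ---------------------------------------------------------------------------
# phage set


@dataclass
class PhageSet:
    """Synthetic phage proteomes with planted RNs and truth."""

    config: SimConfig
    proteomes: dict[str, dict[str, str]]  # phage id -> {protein id: seq}
    hits: dict[str, list[DomainHit]]
    truth: pd.DataFrame

    def write(self, out_dir: str | os.PathLike) -> None:
        out = os.fspath(out_dir)
        os.makedirs(os.path.join(out, "proteomes"), exist_ok=True)
        os.makedirs(os.path.join(out, "hits"), exist_ok=True)
        for pid in sorted(self.proteomes):
            write_protein_fasta(
                self.proteomes[pid], os.path.join(out, "proteomes", f"{pid}.faa")
            )
            write_domtbl(self.hits.get(pid, []), os.path.join(out, "hits", f"{pid}.domtbl"))
        self.truth.to_csv(os.path.join(out, "phage_truth.tsv"), sep="\t", index=False)


def generate_phage_set(
    config: SimConfig, families: Mapping[str, SyntheticFamily] | None = None
) -> PhageSet:
    """Phage proteomes at toy scale, deterministic given the seed.

    A ``phage_rn_fraction`` of phages carry one planted RN whose family
    follows ``phage_rn_weights`` (dominated by Crn2, the viral
    anti-CRISPR homologue).  ``n_phage_missing_residue`` of the planted
    RNs have a conserved residue broken and must fail the screen.
    """
    families = dict(families) if families else make_families(config)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 23]))
    proteomes: dict[str, dict[str, str]] = {}
    hits: dict[str, list[DomainHit]] = {}
    rows: list[dict] = []
    carriers = 0
    broken_left = config.n_phage_missing_residue
    for i in range(1, config.n_phage + 1):
        pid = f"P{i:04d}"
        lo, hi = config.phage_proteome_size
        n_prot = int(rng.integers(lo, hi + 1))
        prots = {
            f"{pid}_p{j:03d}": _rand_protein(rng, int(rng.integers(60, 401)))
            for j in range(1, n_prot + 1)
        }
        phage_hits: list[DomainHit] = []
        if rng.random() < config.phage_rn_fraction:
            carriers += 1
            fam = _weighted_choice(rng, config.phage_rn_weights)
            broken = broken_left > 0
            if broken:
                broken_left -= 1
            seq = _family_variant(rng, families[fam], break_conserved=broken)
            prot_id = f"{pid}_rn"
            prots[prot_id] = seq
            phage_hits.append(
                DomainHit(
                    protein_id=prot_id,
                    family_id=fam,
                    bitscore=_real_score(rng),
                    evalue=_real_evalue(rng),
                    ali_start=1,
                    ali_end=len(seq),
                )
            )
            rows.append(
                {
                    "gene_id": prot_id,
                    "genome_id": pid,
                    "locus_id": "",
                    "role": f"rn:{fam}",
                    "family": fam,
                    "expected_verdict": VERDICT_SCREEN if broken else VERDICT_ANNOTATED,
                }
            )
        proteomes[pid] = prots
        hits[pid] = phage_hits
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return PhageSet(config=config, proteomes=proteomes, hits=hits, truth=truth)


# ---------------------------------------------------------------------------
# loading a materialized dataset


def load_dataset_dir(directory: str | os.PathLike):
    """Read back a written dataset: genomes, hits, subtype rows, truth.

    Returns (genomes, hits, subtype_rows, truth_df); reference MSAs are
    loaded separately via :func:`ringscan.annotator.load_reference_msas`.
    """
    from .core_model import parse_domtbl, parse_gff, read_protein_fasta

    out = os.fspath(directory)
    genomes: dict[str, GenomeAnnotation] = {}
    hits: dict[str, list[DomainHit]] = {}
    gdir = os.path.join(out, "genomes")
    for name in sorted(os.listdir(gdir)):
        if not name.endswith(".gff"):
            continue
        gid = name[:-4]
        proteins = read_protein_fasta(os.path.join(gdir, f"{gid}.faa"))
        genomes[gid] = parse_gff(os.path.join(gdir, name), proteins, genome_id=gid)
        hit_path = os.path.join(out, "hits", f"{gid}.domtbl")
        hits[gid] = parse_domtbl(hit_path) if os.path.exists(hit_path) else []
    subtype_rows: dict[str, list[tuple[str, int, int, str]]] = {}
    sub_path = os.path.join(out, "subtypes.tsv")
    if os.path.exists(sub_path):
        df = pd.read_csv(sub_path, sep="\t")
        for row in df.itertuples(index=False):
            subtype_rows.setdefault(row.genome_id, []).append(
                (row.contig, int(row.start), int(row.end), row.subtype)
            )
    truth_path = os.path.join(out, "truth.tsv")
    truth = (
        pd.read_csv(truth_path, sep="\t", keep_default_na=False)
        if os.path.exists(truth_path)
        else pd.DataFrame(columns=TRUTH_COLUMNS)
    )
    return genomes, hits, subtype_rows, truth
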