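"""Independent brute-force oracles used to cross-check the pipeline.

Everything here is deliberately naive (O(n^2) scans, full DP matrices,
line-by-line parsing) and shares no code with the implementation paths
it checks.
"""

from __future__ import annotations

import numpy as np


def brute_force_members(loci, genes):
    """Per-gene scan: nearest cas span among overlapping neighborhoods."""
    assignment: dict[str, list] = {loc.locus_id: [] for loc in loci}
    for g in genes:
        best = None
        best_key = None
        for loc in loci:
            if loc.genome_id != g.genome_id or loc.contig_id != g.contig_id:
                continue
            ns, ne = loc.neighborhood
            if g.end < ns or g.start > ne:
                continue
            ss, se = loc.cas_span
            if g.end >= ss and g.start <= se:
                gap = 0
            elif g.end < ss:
                gap = ss - g.end - 1
            else:
                gap = g.start - se - 1
            key = (gap, loc.locus_id)
            if best_key is None or key < best_key:
                best_key = key
                best = loc
        if best is not None:
            assignment[best.locus_id].append(g.gene_id)
    return {k: sorted(v) for k, v in assignment.items()}


def brute_force_cas_span(anchor, cas_genes, chain_gap):
    """Transitive closure of the <= chain_gap relation over cas genes."""

    def gap(a, b):
        if a.start <= b.end and b.start <= a.end:
            return 0
        return max(a.start, b.start) - min(a.end, b.end) - 1

    pool = [g for g in cas_genes if g.contig_id == anchor.contig_id]
    reached = {anchor.gene_id}
    changed = True
    while changed:
        changed = False
        for a in pool:
            if a.gene_id not in reached:
                continue
            for b in pool:
                if b.gene_id not in reached and gap(a, b) <= chain_gap:
                    reached.add(b.gene_id)
                    changed = True
    chosen = [g for g in pool if g.gene_id in reached]
    return (min(g.start for g in chosen), max(g.end for g in chosen))


def brute_force_edge_weights(loci):
    """Pairwise count of loci containing both an RN and effector family."""
    weights: dict[tuple[str, str], int] = {}
    rn_fams = sorted(
        {r.family for loc in loci for r in loc.rns if r.screen_status != "fail"}
    )
    eff_fams = sorted({e.family for loc in loci for e in loc.effectors})
    for rf in rn_fams:
        for ef in eff_fams:
            n = 0
            for loc in loci:
                has_r = any(
                    r.family == rf and r.screen_status != "fail" for r in loc.rns
                )
                has_e = any(e.family == ef for e in loc.effectors)
                n += has_r and has_e
            if n:
                weights[(rf, ef)] = n
    return weights


def gotoh_global_score(a, b, matrix, gap_open=10, gap_extend=1):
    """Affine-gap global alignment score by full Gotoh DP (terminal gaps
    penalized).  Mirrors standard three-matrix recursion."""
    n, m = len(a), len(b)
    neg = -(10**9)
    M = np.full((n + 1, m + 1), neg, dtype=float)
    X = np.full((n + 1, m + 1), neg, dtype=float)  # gap in b (a consumed)
    Y = np.full((n + 1, m + 1), neg, dtype=float)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1]][b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend, Y[i - 1, j] - gap_open)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend, X[i, j - 1] - gap_open)
    return max(M[n, m], X[n, m], Y[n, m])


def blosum62_lookup():
    """BLOSUM62 as nested dicts, taken from biotite's matrix (the oracle
    checks the alignment algorithm, not the score table)."""
    from biotite.sequence.align import SubstitutionMatrix

    m = SubstitutionMatrix.std_protein_matrix()
    alpha = [str(s) for s in m.get_alphabet1()]
    arr = m.score_matrix()
    return {
        a: {b: int(arr[i, j]) for j, b in enumerate(alpha)}
        for i, a in enumerate(alpha)
    }


def tally_conserved_columns(rows, t_cons=1.0, g_max=0.2):
    """Direct per-column tally of conserved columns (consensus coords)."""
    n = len(rows)
    length = len(rows[0])
    conserved = []
    consensus_idx = 0
    for col in range(length):
        residues = [r[col] for r in rows]
        non_gap = [r for r in residues if r not in "-."]
        if 1.0 - len(non_gap) / n > g_max:
            continue
        counts = {}
        for r in non_gap:
            counts[r] = counts.get(r, 0) + 1
        modal = max(sorted(counts), key=lambda r: counts[r])
        if counts[modal] / len(non_gap) >= t_cons:
            conserved.append((consensus_idx, modal))
        consensus_idx += 1
    return conserved


def mini_domtbl_parse(text):
    """Second, minimal domtbl parser: (n_rows, score_sum, evalue_sum)."""
    n = 0
    score_sum = 0.0
    ev_sum = 0.0
    for line in text.splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split()
        n += 1
        ev_sum += float(parts[12])
        score_sum += float(parts[13])
    return n, score_sum, ev_sum


def random_locus_fixture(rng, n_loci=2, n_genes=25, contig_len=80_000):
    """Random loci + genes on one contig for membership oracle tests."""
    from ringscan.core_model import Cas10Annotation, GeneFeature, Locus
    from ringscan.locus_builder import build_neighborhood

    loci = []
    pos = int(rng.integers(1000, 8000))
    for i in range(n_loci):
        span_len = int(rng.integers(2000, 8000))
        span = (pos, pos + span_len)
        anchor = GeneFeature(
            gene_id=f"anchor{i}", genome_id="G", contig_id="c1",
            start=span[0], end=min(span[1], span[0] + 2000), strand="+",
            protein_seq="M" * 100,
        )
        loci.append(
            Locus(
                locus_id=f"L{i}", genome_id="G", contig_id="c1",
                cas10=Cas10Annotation(anchor, False, False),
                cas_span=span,
                neighborhood=build_neighborhood(span, contig_len),
            )
        )
        pos = span[1] + int(rng.integers(2000, 20_000))
    genes = []
    for j in range(n_genes):
        start = int(rng.integers(1, contig_len - 2000))
        genes.append(
            GeneFeature(
                gene_id=f"g{j:03d}", genome_id="G", contig_id="c1",
                start=start, end=start + int(rng.integers(150, 1800)),
                strand="+", protein_seq="M" * 60,
            )
        )
    return loci, genes
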