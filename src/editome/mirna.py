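"""miRNA target scanning at edited 3'UTR positions and gain/loss calls.

For each 3'UTR editing site two 61-nt transcript-sense queries are built —
the reference (A) and the edited (G) allele — and scanned against mature
miRNA sequences with a two-phase scorer: a seed-weighted local
complementarity alignment (match +5, G:U wobble +2, mismatch -3, affine
gaps -9/-4, miRNA 5' positions 2-8 scaled x4) gated by a nearest-neighbor
duplex-energy estimate. A hit requires alignment score >= 155 and energy
<= -20 kcal/mol and is retained for classification only when it covers the
editing position. The scorer follows the miRanda two-phase architecture but
is an independent implementation: parity with any particular miRanda
release is not claimed, and thresholds are interpreted on this scorer's
scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .types import EditingSite, GeneModel, revcomp

WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE_PAIRS = {("G", "U"), ("U", "G")}

#: Watson-Crick nearest-neighbor stack free energies (kcal/mol, 37 C),
#: keyed by the top-strand dimer 5'-q1 q2-3' (the bottom strand is its
#: Watson-Crick complement). The ten unique values cover all sixteen
#: dimers via the 180-degree duplex rotation q1q2 -> comp(q2)comp(q1).
WC_STACK = {
    "AA": -0.93, "AU": -1.10, "UA": -1.33, "CU": -2.08, "CA": -2.11,
    "GU": -2.24, "GA": -2.35, "CG": -2.36, "GG": -3.26, "GC": -3.42,
}
#: Stacks involving a G:U wobble pair use one pooled value (approximation).
WOBBLE_STACK = -1.2
HELIX_INIT = 4.09
LOOP_PENALTY = 3.0

_RC = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _is_paired(a: str, b: str) -> bool:
    return (a, b) in WC_PAIRS or (a, b) in WOBBLE_PAIRS


def stack_energy(q1: str, q2: str, m1: str, m2: str) -> float:
    """Free energy of stacking pair (q1:m1) on (q2:m2), RNA alphabet."""
    if (q1, m1) in WC_PAIRS and (q2, m2) in WC_PAIRS:
        key = q1 + q2
        if key in WC_STACK:
            return WC_STACK[key]
        return WC_STACK[_RC[q2] + _RC[q1]]
    return WOBBLE_STACK


@dataclass
class ScanParams:
    """Thresholds and scoring table of the target scanner."""

    score_min: float = 155.0
    energy_max_kcal: float = -20.0
    match: float = 5.0
    wobble: float = 2.0
    mismatch: float = -3.0
    gap_open: float = 9.0
    gap_extend: float = 4.0
    seed_scale: float = 4.0
    seed_start: int = 2  # miRNA 5' positions scaled, inclusive
    seed_end: int = 8

    def __post_init__(self) -> None:
        if self.score_min <= 0:
            raise ValueError("score_min must be > 0")
        if self.energy_max_kcal >= 0:
            raise ValueError("energy_max_kcal must be < 0")


@dataclass
class AlleleQueryPair:
    """61-nt transcript-sense queries for the two alleles of one site."""

    site_key: str
    ref_query: str
    edit_query: str
    site_offset: int
    truncated: bool = False

    def __post_init__(self) -> None:
        if len(self.ref_query) != len(self.edit_query):
            raise ValueError("allele queries must have equal length")
        diff = [i for i, (a, b) in enumerate(zip(self.ref_query,
                                                 self.edit_query)) if a != b]
        if diff != [self.site_offset]:
            raise ValueError("queries must differ exactly at site_offset")


@dataclass
class Alignment:
    score: float
    query_span: tuple[int, int]  # 0-based half-open on the query
    mirna_span: tuple[int, int]  # 1-based inclusive miRNA 5' positions
    pairs: list[tuple[int, int, str]] = field(default_factory=list)
    # (query index, miRNA 5' position, 'wc'|'wobble'|'mismatch')


@dataclass
class MiRNAHit:
    mirna_id: str
    allele: str  # 'ref' | 'edit'
    query_span: tuple[int, int]
    score: float
    energy_kcal: float
    covers_site: bool
    alignment: Alignment | None = None


def build_allele_queries(site: EditingSite, ref: dict[str, str],
                         genes: list[GeneModel], flank: int = 30
                         ) -> AlleleQueryPair:
    """Extract transcript-sense reference/edited queries around a site.

    The editing position sits at offset ``flank`` (center) unless the
    window is truncated at a contig end, in which case the offset shifts
    and the pair is flagged. On minus-strand genes the genomic window is
    reverse-complemented so the edited base is always A>G in the query.
    """
    if site.strand not in ("+", "-"):
        raise ValueError(f"site {site.chrom}:{site.pos0 + 1} has unknown "
                         "strand; assign strand before building queries")
    seq = ref[site.chrom]
    lo = max(0, site.pos0 - flank)
    hi = min(len(seq), site.pos0 + flank + 1)
    window = seq[lo:hi].upper()
    offset = site.pos0 - lo
    truncated = (hi - lo) != (2 * flank + 1)
    if site.strand == "-":
        window = revcomp(window)
        offset = len(window) - 1 - offset
    if window[offset] != "A":
        raise ValueError(
            f"site {site.chrom}:{site.pos0 + 1}: transcript-sense reference "
            f"base is {window[offset]!r}, expected A")
    edit = window[:offset] + "G" + window[offset + 1:]
    key = f"{site.chrom}:{site.pos0 + 1}:{site.var_base}"
    return AlleleQueryPair(key, window, edit, offset, truncated)


def _sub_score(qb: str, mb: str, mpos: int, p: ScanParams) -> tuple[float, str]:
    if (qb, mb) in WC_PAIRS:
        s, kind = p.match, "wc"
    elif (qb, mb) in WOBBLE_PAIRS:
        s, kind = p.wobble, "wobble"
    else:
        s, kind = p.mismatch, "mismatch"
    if p.seed_start <= mpos <= p.seed_end:
        s *= p.seed_scale
    return s, kind


def align_mirna(query: str, mirna: str, params: ScanParams | None = None
                ) -> Alignment:
    """Best local alignment of a miRNA (3'->5') against a query (5'->3').

    Smith-Waterman with affine gaps over the query and the reversed miRNA;
    substitution scores follow the complementarity table with seed
    positions scaled. Deterministic: among equal scores the first-reached
    cell in (query, miRNA) scan order wins and traceback prefers pairing
    over gaps.
    """
    p = params or ScanParams()
    q = _rna(query)
    m = _rna(mirna)
    for s in (q, m):
        if any(c not in "ACGU" for c in s):
            raise ValueError(f"non-nucleotide character in {s!r}")
    r = m[::-1]  # r[j] is miRNA 5' position len(m) - j
    Q, M = len(q), len(r)
    NEG = float("-inf")
    H = [[0.0] * (M + 1) for _ in range(Q + 1)]
    E = [[NEG] * (M + 1) for _ in range(Q + 1)]  # gap: query base unpaired
    F = [[NEG] * (M + 1) for _ in range(Q + 1)]  # gap: miRNA base unpaired
    ptr: dict[tuple[int, int, str], tuple] = {}
    best, best_cell = 0.0, None
    for i in range(1, Q + 1):
        Hi, Hi1 = H[i], H[i - 1]
        Ei, Ei1, Fi = E[i], E[i - 1], F[i]
        for j in range(1, M + 1):
            e = max(Hi1[j] - p.gap_open, Ei1[j] - p.gap_extend)
            Ei[j] = e
            f = max(Hi[j - 1] - p.gap_open, Fi[j - 1] - p.gap_extend)
            Fi[j] = f
            mpos = M - j + 1
            s, kind = _sub_score(q[i - 1], r[j - 1], mpos, p)
            diag = Hi1[j - 1] + s
            h = diag
            src = ("diag", kind)
            if e > h:
                h, src = e, ("up",)
            if f > h:
                h, src = f, ("left",)
            if h <= 0.0:
                h, src = 0.0, ("stop",)
            Hi[j] = h
            ptr[(i, j, "H")] = src
            if h > best:
                best, best_cell = h, (i, j)
    if best_cell is None:
        return Alignment(0.0, (0, 0), (0, 0), [])

    # traceback
    pairs: list[tuple[int, int, str]] = []
    i, j = best_cell
    state = "H"
    qi_end = i
    while i > 0 and j > 0:
        if state == "H":
            src = ptr[(i, j, "H")]
            if src[0] == "stop":
                break
            if src[0] == "diag":
                pairs.append((i - 1, M - j + 1, src[1]))
                i, j = i - 1, j - 1
            elif src[0] == "up":
                state = "E"
            else:
                state = "F"
        elif state == "E":
            # gap consuming query base i-1
            if H[i - 1][j] - p.gap_open >= E[i - 1][j] - p.gap_extend:
                state = "H"
            i -= 1
        else:  # F: gap consuming miRNA base j-1
            if H[i][j - 1] - p.gap_open >= F[i][j - 1] - p.gap_extend:
                state = "H"
            j -= 1
    pairs.reverse()
    qi_start = pairs[0][0] if pairs else i
    m_positions = [mp for _, mp, _ in pairs]
    mirna_span = (min(m_positions), max(m_positions)) if m_positions else (0, 0)
    return Alignment(best, (qi_start, qi_end), mirna_span, pairs)


def duplex_energy(alignment: Alignment, query: str, mirna: str) -> float:
    """Nearest-neighbor duplex free-energy estimate for an alignment.

    Sums stack energies over consecutive paired positions (WC or wobble),
    adds one helix-initiation term and a fixed penalty per helix
    interruption (internal loop/bulge/mismatch). More pairing gives lower
    (more negative) energy. No pairs at all gives 0.
    """
    q = _rna(query)
    m = _rna(mirna)
    paired = [(qi, mp) for qi, mp, kind in alignment.pairs
              if kind in ("wc", "wobble")]
    if not paired:
        return 0.0
    energy = HELIX_INIT
    for (qi1, mp1), (qi2, mp2) in zip(paired, paired[1:]):
        if qi2 == qi1 + 1 and mp2 == mp1 - 1:
            energy += stack_energy(q[qi1], q[qi2], m[mp1 - 1], m[mp2 - 1])
        else:
            energy += LOOP_PENALTY
    return energy


def scan_targets(pair: AlleleQueryPair, mirnas: dict[str, str],
                 params: ScanParams | None = None) -> list[MiRNAHit]:
    """Scan both allele queries against a miRNA set.

    A hit is emitted iff score >= score_min and energy <= energy_max_kcal;
    ``covers_site`` marks hits whose query span includes the site offset.
    """
    p = params or ScanParams()
    hits: list[MiRNAHit] = []
    for allele, query in (("ref", pair.ref_query), ("edit", pair.edit_query)):
        for mirna_id, seq in mirnas.items():
            aln = align_mirna(query, seq, p)
            if aln.score < p.score_min:
                continue
            energy = duplex_energy(aln, query, seq)
            if energy > p.energy_max_kcal:
                continue
            covers = aln.query_span[0] <= pair.site_offset < aln.query_span[1]
            hits.append(MiRNAHit(mirna_id, allele, aln.query_span, aln.score,
                                 energy, covers, aln))
    return hits


def classify_target_change(ref_hits: list[MiRNAHit],
                           edit_hits: list[MiRNAHit],
                           mirna_ids=None) -> dict[str, str]:
    """Per-miRNA gain/loss classification from site-covering hits.

    gain: covering hit on the edited allele only; loss: on the reference
    allele only; present_both / absent_both otherwise. ``mirna_ids``
    optionally fixes the universe (absent_both reported for misses).
    """
    ref_cov = {h.mirna_id for h in ref_hits if h.covers_site}
    edit_cov = {h.mirna_id for h in edit_hits if h.covers_site}
    ids = set(mirna_ids) if mirna_ids is not None else (ref_cov | edit_cov)
    out = {}
    for mid in sorted(ids):
        if mid in edit_cov and mid not in ref_cov:
            out[mid] = "gain"
        elif mid in ref_cov and mid not in edit_cov:
            out[mid] = "loss"
        elif mid in ref_cov:
            out[mid] = "present_both"
        else:
            out[mid] = "absent_both"
    return out


def retarget_sites(sites: list[EditingSite], ref: dict[str, str],
                   genes: list[GeneModel], mirnas: dict[str, str],
                   params: ScanParams | None = None):
    """End-to-end retargeting: queries, scan, classify, per site.

    Returns a list of dict rows (site, mirna, change_class, per-allele
    score/energy where available).
    """
    import pandas as pd

    p = params or ScanParams()
    rows = []
    for site in sites:
        pair = build_allele_queries(site, ref, genes)
        hits = scan_targets(pair, mirnas, p)
        ref_hits = [h for h in hits if h.allele == "ref"]
        edit_hits = [h for h in hits if h.allele == "edit"]
        changes = classify_target_change(ref_hits, edit_hits)
        for mid, cls in changes.items():
            rows.append({"site": pair.site_key, "mirna": mid,
                         "change_class": cls})
    return pd.DataFrame(rows, columns=["site", "mirna", "change_class"])
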