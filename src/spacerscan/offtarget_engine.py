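"""Fully sensitive off-target search for 20-nt spacers.

The engine aligns a query spacer against every PAM-adjacent candidate window
in a genome, allowing mismatches and single-base bulges (gaps).  Candidate
windows are anchored at the PAM-proximal end and vary in length from
``spacer_len - max_gaps`` to ``spacer_len + max_gaps`` so that bulges are
absorbed at the PAM-distal side:

* an *RNA bulge* is a guide base with no genomic partner (the site carries a
  deletion relative to the spacer);
* a *DNA bulge* is an extra genomic base with no guide partner (the site
  carries an insertion).

Bulges are isolated unpaired bases within an otherwise paired duplex, so two
gap columns never sit next to each other in an alignment: a two-base
insertion would be a multi-base bulge (out of budget by construction), and
an insertion adjacent to a deletion is just a mismatch.

Differences are counted with unit cost — each mismatch and each single-base
bulge contributes 1 — and positions are numbered from the PAM-proximal end
(position 1 is adjacent to the PAM), where mismatches most strongly abolish
Cas9 cleavage.  ``seed10``/``seed15`` count differences within the first
10/15 positions.

Exhaustive mode misses nothing within the difference budget; seeded mode
first requires the candidate window to share an exact k-mer ("word") with
the query, reproducing the behaviour — and the blind spots — of word-seeded
aligners on short queries.

An independent bounded-edit-distance brute-force oracle
(:func:`brute_force_oracle`) re-derives hit sets from first principles for
testing; it shares no code path with the engine.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple

import numpy as np

from .pam_scanner import PAM_NAG, PAM_NGG, SpacerSite, scan_pam_sites
from .sequence_io import Genome

SEED_SHORT = 10  # nt, conservative PAM-proximal seed
SEED_LONG = 15  # nt, extended seed

RNA_BULGE = "rna_bulge"
DNA_BULGE = "dna_bulge"

_INF = 10_000
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_INVALID = 4  # N or out-of-bounds: may never be aligned


@dataclass(frozen=True)
class SearchParams:
    """Difference budget and search-mode configuration.

    ``max_mismatches`` and ``max_gaps`` bound each alignment separately: a
    hit needs some alignment with at most ``max_mismatches`` mismatches AND
    at most ``max_gaps`` single-base bulges.
    """

    max_mismatches: int = 4
    max_gaps: int = 2
    mode: str = "exhaustive"
    word_size: int = 5
    pam_classes: frozenset[str] = frozenset({PAM_NGG})

    def __post_init__(self) -> None:
        if not 0 <= self.max_gaps <= 2:
            raise ValueError("max_gaps must be in [0, 2]")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.mode not in ("exhaustive", "seeded"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.word_size < 1:
            raise ValueError("word_size must be >= 1")
        if not set(self.pam_classes) <= {PAM_NGG, PAM_NAG}:
            raise ValueError("pam_classes must be a subset of {NGG, NAG}")
        object.__setattr__(self, "pam_classes", frozenset(self.pam_classes))


@dataclass(frozen=True)
class DifferenceProfile:
    """Mismatch/bulge positions of one alignment, numbered from the PAM.

    Position 1 is the PAM-proximal spacer base.  A bulge lying between spacer
    positions p and p+1 is assigned position p+1 (toward the seed), so seed
    counts never overstate specificity.
    """

    mismatch_positions: frozenset[int]
    gap_positions: frozenset[tuple[int, str]]
    total: int
    seed10: int
    seed15: int

    def __post_init__(self) -> None:
        if self.total != len(self.mismatch_positions) + len(self.gap_positions):
            raise ValueError("total must equal mismatches + gap bases")
        if not 0 <= self.seed10 <= self.seed15 <= self.total:
            raise ValueError("seed counts must satisfy 0 <= seed10 <= seed15 <= total")

    @classmethod
    def from_positions(
        cls,
        mismatch_positions: Iterable[int],
        gap_positions: Iterable[tuple[int, str]] = (),
    ) -> "DifferenceProfile":
        mm = frozenset(mismatch_positions)
        gp = frozenset(gap_positions)
        positions = list(mm) + [p for p, _ in gp]
        return cls(
            mismatch_positions=mm,
            gap_positions=gp,
            total=len(mm) + len(gp),
            seed10=sum(1 for p in positions if p <= SEED_SHORT),
            seed15=sum(1 for p in positions if p <= SEED_LONG),
        )

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatch_positions)

    @property
    def n_gaps(self) -> int:
        return len(self.gap_positions)


EMPTY_PROFILE = DifferenceProfile.from_positions(())


@dataclass(frozen=True)
class Alignment:
    """A gapped pairwise alignment, 5'->3', with its difference profile.

    For global alignments both rows cover their full strings.  For local
    alignments the rows are the best-scoring ungapped segment and
    ``query_start``/``subject_start`` give its 0-based offsets.
    """

    aligned_query: str
    aligned_subject: str
    profile: DifferenceProfile
    query_start: int = 0
    subject_start: int = 0


@dataclass(frozen=True)
class OffTargetHit:
    query: str
    site: SpacerSite
    profile: DifferenceProfile
    alignment_mode: str = "global"
    alignment: Alignment | None = None


class OracleHit(NamedTuple):
    """Minimal hit record produced by the brute-force oracle."""

    seq_name: str
    start: int
    end: int
    strand: str
    pam_class: str
    total: int
    mismatches: int
    gaps: int


def diff_profile(alignment: Alignment, spacer_len: int = 20) -> DifferenceProfile:
    """Difference profile of a global alignment, PAM-proximal numbering.

    Walks the alignment columns from the PAM-proximal (3') end.  A query base
    opposite a gap is an RNA bulge at that base's position; a subject base
    opposite a gap is a DNA bulge assigned the position of the next
    PAM-distal query base.
    """
    aq, asu = alignment.aligned_query, alignment.aligned_subject
    if len(aq) != len(asu):
        raise ValueError("alignment rows differ in length")
    mismatches: list[int] = []
    gaps: list[tuple[int, str]] = []
    p = 0  # query bases consumed from the PAM-proximal end
    prev_gap = False
    for qc, sc in zip(reversed(aq), reversed(asu)):
        if qc == "-" and sc == "-":
            raise ValueError("gap in both alignment rows")
        if "-" in (qc, sc):
            if prev_gap:
                raise ValueError("adjacent gap columns: bulges must be isolated")
            prev_gap = True
        else:
            prev_gap = False
        if qc != "-" and sc != "-":
            p += 1
            if qc != sc:
                mismatches.append(p)
        elif sc == "-":  # query base unpaired: RNA bulge
            p += 1
            gaps.append((p, RNA_BULGE))
        else:  # subject base unpaired: DNA bulge, pushed toward the seed
            gaps.append((p + 1, DNA_BULGE))
    return DifferenceProfile.from_positions(mismatches, gaps)


# ---------------------------------------------------------------------------
# Global alignment (exact DP with per-gap-count layers and seed tie-breaks)
# ---------------------------------------------------------------------------

class _LayerResult(NamedTuple):
    mismatches: int
    seed10: int
    seed15: int
    aligned_query: str  # 5'->3'
    aligned_subject: str


def _align_layers(query: str, window: str, max_gaps: int) -> dict[int, _LayerResult]:
    """Optimal alignments of ``query`` vs ``window`` per exact gap count.

    Both strings are full-length aligned (global).  For each g in
    [0, max_gaps], returns the alignment with exactly g single-base bulges
    minimizing (mismatches, seed10, seed15) lexicographically — the
    least-seed-disrupted, hence most threatening, interpretation.  Layers
    that cannot be realized (wrong length parity or insufficient gaps) are
    omitted.
    """
    q = query[::-1]  # PAM-proximal first
    w = window[::-1]
    n, m = len(q), len(w)
    BIG = (_INF, _INF, _INF)
    # D[g][i][j][last] = best (mm, seed10, seed15), where last flags that the
    # previous column was a gap: bulges are isolated unpaired bases, so two
    # gap columns may never be adjacent (a 2-nt insertion is a multi-base
    # bulge, and an insertion next to a deletion is just a mismatch).
    D = [
        [[[BIG, BIG] for _ in range(m + 1)] for _ in range(n + 1)]
        for _ in range(max_gaps + 1)
    ]
    parent: dict[tuple[int, int, int, int], tuple[int, int, int, int, str]] = {}
    D[0][0][0][0] = (0, 0, 0)
    for g in range(max_gaps + 1):
        for i in range(n + 1):
            for j in range(m + 1):
                for last in (0, 1):
                    cur = D[g][i][j][last]
                    if cur == BIG:
                        continue
                    if i < n and j < m:  # match / mismatch at position i+1
                        mmc = 1 if q[i] != w[j] else 0
                        cand = (
                            cur[0] + mmc,
                            cur[1] + (mmc if i + 1 <= SEED_SHORT else 0),
                            cur[2] + (mmc if i + 1 <= SEED_LONG else 0),
                        )
                        if cand < D[g][i + 1][j + 1][0]:
                            D[g][i + 1][j + 1][0] = cand
                            parent[(g, i + 1, j + 1, 0)] = (g, i, j, last, "D")
                    if g < max_gaps and last == 0:
                        if i < n:  # RNA bulge: query base i+1 unpaired
                            cand = (
                                cur[0],
                                cur[1] + (1 if i + 1 <= SEED_SHORT else 0),
                                cur[2] + (1 if i + 1 <= SEED_LONG else 0),
                            )
                            if cand < D[g + 1][i + 1][j][1]:
                                D[g + 1][i + 1][j][1] = cand
                                parent[(g + 1, i + 1, j, 1)] = (g, i, j, last, "R")
                        if j < m:  # DNA bulge between query positions i and i+1
                            cand = (
                                cur[0],
                                cur[1] + (1 if i + 1 <= SEED_SHORT else 0),
                                cur[2] + (1 if i + 1 <= SEED_LONG else 0),
                            )
                            if cand < D[g + 1][i][j + 1][1]:
                                D[g + 1][i][j + 1][1] = cand
                                parent[(g + 1, i, j + 1, 1)] = (g, i, j, last, "B")
    out: dict[int, _LayerResult] = {}
    for g in range(max_gaps + 1):
        finals = [(D[g][n][m][last], last) for last in (0, 1)]
        (score, last) = min(finals)
        if score == BIG:
            continue
        mm, s10, s15 = score
        # Traceback (proximal-first), then flip to 5'->3'.
        cols_q: list[str] = []
        cols_s: list[str] = []
        state = (g, n, m, last)
        while state[:3] != (0, 0, 0):
            pg, pi, pj, plast, move = parent[state]
            if move == "D":
                cols_q.append(q[pi])
                cols_s.append(w[pj])
            elif move == "R":
                cols_q.append(q[pi])
                cols_s.append("-")
            else:
                cols_q.append("-")
                cols_s.append(w[pj])
            state = (pg, pi, pj, plast)
        out[g] = _LayerResult(mm, s10, s15, "".join(cols_q), "".join(cols_s))
    return out


def align_global(query: str, window: str, max_gaps: int = 2) -> Alignment:
    """Full-length alignment minimizing total differences (unit costs).

    At most ``max_gaps`` single-base bulges are allowed; ties among
    minimal-total alignments are broken by fewer gaps, then fewest seed10
    differences, then fewest seed15 (the most threatening interpretation of
    the site).
    """
    if abs(len(window) - len(query)) > max_gaps:
        raise ValueError(
            f"length difference {abs(len(window) - len(query))} exceeds "
            f"max_gaps={max_gaps}"
        )
    layers = _align_layers(query, window, max_gaps)
    g, res = min(layers.items(), key=lambda kv: (kv[1].mismatches + kv[0], kv[0], kv[1].seed10, kv[1].seed15))
    aln = Alignment(res.aligned_query, res.aligned_subject, EMPTY_PROFILE)
    return replace(aln, profile=diff_profile(aln, spacer_len=len(query)))


def align_local(query: str, window: str) -> Alignment:
    """Best ungapped local alignment (match +1, mismatch -2).

    Models the behaviour of a local aligner on a bulged site: rather than
    absorbing the gap it splits the match into sub-segments, and the best
    segment is reported.  The profile counts only differences inside the
    segment, at PAM-proximal positions of the full query.
    """
    n, m = len(query), len(window)
    best = None  # (score, length, -offset, -qstart) maximized
    for off in range(-(n - 1), m):
        lo = max(0, -off)
        hi = min(n, m - off)
        run_score, run_start = 0, lo
        for i in range(lo, hi):
            s = 1 if query[i] == window[i + off] else -2
            if run_score + s < s:  # restart the segment
                run_score, run_start = s, i
            else:
                run_score += s
            cand = (run_score, i + 1 - run_start, -off, -run_start)
            if best is None or cand > best:
                best = (*cand, run_start, i + 1)
    if best is None:
        return Alignment("", "", EMPTY_PROFILE)
    _score, _length, noff, _nqs, qs, qe = best
    off = -noff
    seg_q = query[qs:qe]
    seg_s = window[qs + off : qe + off]
    mismatches = [n - i for i in range(qs, qe) if query[i] != window[i + off]]
    return Alignment(
        aligned_query=seg_q,
        aligned_subject=seg_s,
        profile=DifferenceProfile.from_positions(mismatches),
        query_start=qs,
        subject_start=qs + off,
    )


# ---------------------------------------------------------------------------
# Candidate window extraction
# ---------------------------------------------------------------------------

def candidate_window(genome: Genome, site: SpacerSite, length: int) -> str | None:
    """The PAM-anchored window of ``length`` nt at a site, 5'->3' on its strand.

    The window ends immediately 5' of the PAM and extends PAM-distally; it is
    the protospacer when ``length`` equals the spacer length.  Returns None
    when the window runs out of sequence or contains N.
    """
    iv = site.interval
    seq = genome[iv.seq_name]
    if iv.strand == "+":
        start = iv.end - length
        if start < 0:
            return None
        window = seq[start : iv.end]
    else:
        end = iv.start + length
        if end > len(seq):
            return None
        window = _revcomp_fast(seq[iv.start : end])
    return None if "N" in window else window


_RC = str.maketrans("ACGTN", "TGCAN")


def _revcomp_fast(seq: str) -> str:
    return seq.translate(_RC)[::-1]


# ---------------------------------------------------------------------------
# Vectorized engine
# ---------------------------------------------------------------------------

class OffTargetSearcher:
    """Reusable searcher: encodes candidate windows once, searches many queries.

    Candidate windows are stored PAM-proximal-first as integer codes in a
    (n_sites, spacer_len + max_gaps) matrix; a banded dynamic program over
    (query position, window offset, gap count) runs vectorized across all
    sites at once.  Cells that fall outside the sequence or on an N are
    marked invalid and can never be aligned.
    """

    def __init__(
        self,
        genome: Genome,
        sites: list[SpacerSite],
        params: SearchParams,
    ) -> None:
        self.genome = genome
        self.params = params
        self.candidates = [s for s in sites if s.pam_class in params.pam_classes]
        G = params.max_gaps
        self._ext_len = None
        self._matrix = None
        self._ext_strings: list[str] = []
        if self.candidates:
            Lq = self.candidates[0].spacer_len
            cols = Lq + G
            mat = np.full((len(self.candidates), cols), _INVALID, dtype=np.uint8)
            lut = np.full(256, _INVALID, dtype=np.uint8)
            for base, code in _CODE.items():
                lut[ord(base)] = code
            for r, site in enumerate(self.candidates):
                iv = site.interval
                seq = self.genome[iv.seq_name]
                if iv.strand == "+":
                    start = max(0, iv.end - cols)
                    chunk = seq[start : iv.end]
                    codes = lut[np.frombuffer(chunk.encode(), dtype=np.uint8)][::-1]
                else:
                    end = min(len(seq), iv.start + cols)
                    chunk = seq[iv.start : end]
                    codes = lut[np.frombuffer(chunk.encode(), dtype=np.uint8)]
                    codes = np.where(codes == _INVALID, _INVALID, 3 - codes)
                mat[r, : len(codes)] = codes
                # Forward (5'->3' on the site strand) string for word seeding;
                # invalid cells render as N and never match an ACGT word.
                fwd = codes[::-1]
                pad = "N" * (cols - len(fwd))
                self._ext_strings.append(pad + "".join("ACGTN"[c] for c in fwd))
            self._matrix = mat
            self._ext_len = cols

    def search(self, query: str, exclude_key: tuple | None = None) -> list[OffTargetHit]:
        """All candidate sites within the difference budget of ``query``."""
        if not self.candidates:
            return []
        params = self.params
        G, M = params.max_gaps, params.max_mismatches
        Lq = len(query)
        active = np.ones(len(self.candidates), dtype=bool)
        if exclude_key is not None:
            for r, site in enumerate(self.candidates):
                if site.key() == exclude_key:
                    active[r] = False
        if params.mode == "seeded":
            w = params.word_size
            words = {query[i : i + w] for i in range(Lq - w + 1)}
            for r, ext in enumerate(self._ext_strings):
                if active[r] and not any(word in ext for word in words):
                    active[r] = False
        feasible = self._feasible_mask(query)
        hits: list[OffTargetHit] = []
        for r in np.flatnonzero(active & feasible):
            hit = self._score_site(query, self.candidates[int(r)])
            if hit is not None:
                hits.append(hit)
        hits.sort(key=lambda h: h.site.key())
        return hits

    def _feasible_mask(self, query: str) -> np.ndarray:
        """Vectorized banded DP: which sites admit a within-budget alignment."""
        params = self.params
        G, M = params.max_gaps, params.max_mismatches
        Lq = len(query)
        W = self._matrix
        n = W.shape[0]
        qcodes = np.array([_CODE.get(b, _INVALID) for b in query[::-1]], dtype=np.uint8)
        INF = np.int32(_INF)
        # State cost D[(g, d, last)] for d = window_consumed - query_consumed;
        # last flags that the previous column was a gap (gap columns may not
        # be adjacent: bulges are isolated unpaired bases).
        def fresh():
            return {
                (g, d, last): np.full(n, INF, dtype=np.int32)
                for g in range(G + 1)
                for d in range(-g, g + 1)
                for last in (0, 1)
            }

        D = fresh()
        D[(0, 0, 0)] = np.zeros(n, dtype=np.int32)

        for i in range(Lq + 1):
            # DNA-bulge step at fixed query index i (no chains: the bulge
            # must be followed by an aligned column).
            for g in range(G):
                for d in range(-g, g + 1):
                    j = i + d
                    if not 0 <= j < W.shape[1]:
                        continue
                    cost = np.where(W[:, j] == _INVALID, INF, np.int32(1))
                    cand = D[(g, d, 0)] + cost
                    key = (g + 1, d + 1, 1)
                    np.minimum(D[key], cand, out=D[key])
            if i == Lq:
                break
            N = fresh()
            for g in range(G + 1):
                for d in range(-g, g + 1):
                    j = i + d
                    if 0 <= j < W.shape[1]:
                        col = W[:, j]
                        step = np.where(
                            col == _INVALID, INF, (col != qcodes[i]).astype(np.int32)
                        )
                        for last in (0, 1):
                            cand = D[(g, d, last)] + step
                            np.minimum(N[(g, d, 0)], cand, out=N[(g, d, 0)])
                    if g < G:  # RNA bulge: consume query base only
                        key = (g + 1, d - 1, 1)
                        cand = D[(g, d, 0)] + 1
                        np.minimum(N[key], cand, out=N[key])
            D = N
        feasible = np.zeros(n, dtype=bool)
        for g in range(G + 1):
            layer = np.full(n, INF, dtype=np.int32)
            for d in range(-g, g + 1):
                for last in (0, 1):
                    np.minimum(layer, D[(g, d, last)], out=layer)
            # layer holds mm + g for exactly g gaps
            feasible |= (layer - g) <= M
        return feasible

    def _score_site(self, query: str, site: SpacerSite) -> OffTargetHit | None:
        """Exact alignment + profile for one feasible site.

        Considers every available window length; among within-budget
        alignments picks the minimal (total, gaps, seed10, seed15), breaking
        remaining ties toward the window length closest to the spacer length.
        """
        params = self.params
        G, M = params.max_gaps, params.max_mismatches
        Lq = len(query)
        best_key = None
        best = None
        for length in range(Lq - G, Lq + G + 1):
            window = candidate_window(self.genome, site, length)
            if window is None:
                continue
            for g, res in _align_layers(query, window, G).items():
                if res.mismatches > M:
                    continue
                key = (
                    res.mismatches + g,
                    g,
                    res.seed10,
                    res.seed15,
                    abs(length - Lq),
                    length,
                )
                if best_key is None or key < best_key:
                    best_key = key
                    best = (res, window)
        if best is None:
            return None
        res, _window = best
        aln = Alignment(res.aligned_query, res.aligned_subject, EMPTY_PROFILE)
        aln = replace(aln, profile=diff_profile(aln, spacer_len=Lq))
        return OffTargetHit(
            query=query,
            site=site,
            profile=aln.profile,
            alignment_mode="global",
            alignment=aln,
        )


def search_offtargets(
    query_site: SpacerSite,
    genome: Genome,
    sites: list[SpacerSite],
    params: SearchParams = SearchParams(),
) -> list[OffTargetHit]:
    """Off-target hits of a query spacer site against scanned candidate sites.

    The query's own locus (exact interval and strand) is excluded; identical
    sequences elsewhere in the genome are genuine 0-difference off-targets.
    """
    iv = query_site.interval
    if iv.seq_name not in genome:
        raise ValueError(f"query site on unknown sequence {iv.seq_name!r}")
    observed = candidate_window(genome, query_site, query_site.spacer_len)
    if observed != query_site.protospacer:
        raise ValueError("query site does not match the genome sequence")
    searcher = OffTargetSearcher(genome, sites, params)
    return searcher.search(query_site.protospacer, exclude_key=query_site.key())


def search_spacer(
    query: str,
    genome: Genome,
    sites: list[SpacerSite] | None = None,
    params: SearchParams = SearchParams(),
) -> list[OffTargetHit]:
    """Off-target hits for a bare spacer sequence (no self-exclusion)."""
    if sites is None:
        sites = scan_pam_sites(genome, params.pam_classes, spacer_len=len(query))
    searcher = OffTargetSearcher(genome, sites, params)
    return searcher.search(query)


# ---------------------------------------------------------------------------
# Independent brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_oracle(
    query: str,
    genome: Genome,
    params: SearchParams = SearchParams(),
    exclude: tuple | None = None,
) -> list[OracleHit]:
    """Reference off-target search by exhaustive bounded edit-distance DP.

    Slides over every PAM-adjacent position on both strands (the minus strand
    is scanned on the reverse-complemented sequence, so the logic is
    strand-uniform and independent of the engine's window encoding).  Each
    allowed window length is screened with edlib's unconstrained edit
    distance — a lower bound on any gap-limited alignment cost — and
    survivors get an exact textbook DP that splits the budget into
    mismatches and gaps.  Intended for test-scale genomes (<= 1 Mb).
    """
    import edlib

    from .sequence_io import reverse_complement

    G, M = params.max_gaps, params.max_mismatches
    Lq = len(query)
    prescreen_k = M + G
    hits: list[OracleHit] = []
    for name, fwd in genome.records.items():
        L = len(fwd)
        for strand, seq in (("+", fwd), ("-", reverse_complement(fwd))):
            for q in range(Lq, L - 2):
                pam = seq[q : q + 3]
                if any(c not in "ACGT" for c in pam):
                    continue
                if pam[1:] == "GG" and PAM_NGG in params.pam_classes:
                    pam_class = PAM_NGG
                elif pam[1:] == "AG" and PAM_NAG in params.pam_classes:
                    pam_class = PAM_NAG
                else:
                    continue
                proto20 = seq[q - Lq : q]
                if "N" in proto20:
                    continue
                if strand == "+":
                    key = (name, q - Lq, q, "+")
                else:
                    key = (name, L - q, L - q + Lq, "-")
                if key == exclude:
                    continue
                best = None  # (total, mm, g)
                for length in range(Lq - G, Lq + G + 1):
                    if q - length < 0:
                        continue
                    window = seq[q - length : q]
                    if "N" in window:
                        continue
                    ed = edlib.align(query, window, mode="NW")["editDistance"]
                    if ed > prescreen_k:
                        continue
                    for g, mm in _oracle_layers(query, window, G).items():
                        if mm > M:
                            continue
                        cand = (mm + g, mm, g)
                        if best is None or cand < best:
                            best = cand
                if best is not None:
                    total, mm, g = best
                    hits.append(
                        OracleHit(key[0], key[1], key[2], key[3], pam_class, total, mm, g)
                    )
    hits.sort(key=lambda h: (h.seq_name, h.start, h.strand, h.pam_class))
    return hits


def _oracle_layers(query: str, window: str, max_gaps: int) -> dict[int, int]:
    """Textbook global DP: minimal mismatches for each exact gap count.

    Gap columns may not be adjacent (single-base bulges only), tracked by a
    trailing-gap flag.
    """
    n, m = len(query), len(window)
    D = [
        [[[_INF, _INF] for _ in range(max_gaps + 1)] for _ in range(m + 1)]
        for _ in range(n + 1)
    ]
    D[0][0][0][0] = 0
    for i in range(n + 1):
        for j in range(m + 1):
            for g in range(max_gaps + 1):
                for last in (0, 1):
                    cur = D[i][j][g][last]
                    if cur >= _INF:
                        continue
                    if i < n and j < m:
                        cost = cur + (0 if query[i] == window[j] else 1)
                        if cost < D[i + 1][j + 1][g][0]:
                            D[i + 1][j + 1][g][0] = cost
                    if g < max_gaps and last == 0:
                        if i < n and cur < D[i + 1][j][g + 1][1]:
                            D[i + 1][j][g + 1][1] = cur
                        if j < m and cur < D[i][j + 1][g + 1][1]:
                            D[i][j + 1][g + 1][1] = cur
    out = {}
    for g in range(max_gaps + 1):
        best = min(D[n][m][g])
        if best < _INF:
            out[g] = best
    return out
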