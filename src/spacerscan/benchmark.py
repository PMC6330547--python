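"""Planted-off-target benchmark and word-size sensitivity analysis.

The benchmark plants, in a synthetic random background, a 20-nt target
spacer plus seven off-target variants carrying zero to four mismatches or
one to two single-base gaps, each followed by an NGG PAM.  Mismatches and
gaps are *equally spaced out* — the placement that minimizes the longest
unaltered run and is therefore the hardest case for word-seeded aligners:
a seeded search can only find a variant whose longest intact run is at
least the word size.  ``max_guaranteed_wordsize`` gives the largest word
size that still guarantees detection of every placement of d differences.

The background is an i.i.d. random sequence at a configurable GC content
(default 0.44, rice-like); construction rejects and redraws backgrounds
until the only windows within the default difference budget of the target
are the planted ones, so the truth set is exact.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .offtarget_engine import (
    DNA_BULGE,
    RNA_BULGE,
    DifferenceProfile,
    SearchParams,
    search_offtargets,
)
from .pam_scanner import PAM_NAG, PAM_NGG, SpacerSite, scan_pam_sites
from .sequence_io import Genome, Interval

#: Variant kinds of the default plan: 0-4 equally spaced mismatches,
#: 1-2 equally spaced single-base deletions (RNA-bulge off-targets).
DEFAULT_VARIANT_PLAN = ("mm0", "mm1", "mm2", "mm3", "mm4", "gap1", "gap2")

#: Insertion (DNA-bulge) variants, added when both bulge directions are wanted.
DNA_BULGE_VARIANTS = ("ins1", "ins2")

_BASES = "ACGT"


class GenerationError(RuntimeError):
    """Background rejection sampling failed; the spec is too permissive."""


@dataclass(frozen=True)
class BenchmarkSpec:
    background_length: int = 100_000
    gc_content: float = 0.44
    rng_seed: int = 0
    spacer: str | None = None  # default: drawn from the background distribution
    variant_plan: tuple[str, ...] = DEFAULT_VARIANT_PLAN

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        min_len = 200 + len(self.variant_plan) * 130 + 200
        if self.background_length < min_len:
            raise ValueError(
                f"background_length must be >= {min_len} to space "
                f"{len(self.variant_plan)} planted variants 100 nt apart"
            )


@dataclass(frozen=True)
class PlantedVariant:
    kind: str
    site: SpacerSite  # the 20-nt PAM-anchored window at the planted locus
    expected: DifferenceProfile
    planted_seq: str  # the genomic variant sequence (18-22 nt, PAM excluded)


@dataclass
class BenchmarkTruth:
    genome: Genome
    target_site: SpacerSite
    planted: list[PlantedVariant] = field(default_factory=list)


@dataclass
class DetectionReport:
    params: SearchParams
    per_variant: list[dict]

    @property
    def n_planted(self) -> int:
        return len(self.per_variant)

    @property
    def detected(self) -> int:
        return sum(1 for v in self.per_variant if v["detected"])

    @property
    def missed(self) -> int:
        return self.n_planted - self.detected

    def to_dict(self) -> dict:
        p = self.params
        return {
            "params": {
                "max_mismatches": p.max_mismatches,
                "max_gaps": p.max_gaps,
                "mode": p.mode,
                "word_size": p.word_size,
                "pam_classes": sorted(p.pam_classes),
            },
            "n_planted": self.n_planted,
            "detected": self.detected,
            "missed": self.missed,
            "per_variant": self.per_variant,
        }


def _max_run(L: int, positions: tuple[int, ...]) -> int:
    """Longest run of unaltered bases when 1-based ``positions`` are altered."""
    run = 0
    prev = 0
    for p in positions:
        run = max(run, p - prev - 1)
        prev = p
    return max(run, L - prev)


def equally_spaced_positions(L: int, d: int) -> tuple[int, ...]:
    """The adversarial placement of d differences in an L-mer.

    Returns the 1-based positions minimizing the maximum run of unaltered
    bases; among minimizers the lexicographically smallest position vector
    is chosen, by exhaustive enumeration.
    """
    if d < 0 or d >= L:
        raise ValueError(f"need 0 <= d < L, got d={d}, L={L}")
    if d == 0:
        return ()
    best = None
    best_run = L + 1
    for combo in itertools.combinations(range(1, L + 1), d):
        r = _max_run(L, combo)
        if r < best_run:
            best_run, best = r, combo
    return best


def min_max_run_bruteforce(L: int, d: int) -> int:
    """min over all placements of d differences of the longest intact run."""
    if d < 0 or d >= L:
        raise ValueError(f"need 0 <= d < L, got d={d}, L={L}")
    if d == 0:
        return L
    return min(_max_run(L, c) for c in itertools.combinations(range(1, L + 1), d))


def max_guaranteed_wordsize(L: int, d: int, verify: bool = False) -> int:
    """Largest word size w that detects EVERY placement of d differences.

    Every placement of d differences in an L-mer leaves an unaltered run of
    at least ceil((L-d)/(d+1)) bases, and the equally spaced placement
    achieves exactly that, so no larger word is guaranteed.  With
    ``verify=True`` the closed form is checked against brute-force
    enumeration of all placements.
    """
    if d < 0 or d >= L:
        raise ValueError(f"need 0 <= d < L, got d={d}, L={L}")
    w = -((L - d) // -(d + 1))  # ceil((L - d) / (d + 1))
    if verify:
        brute = min_max_run_bruteforce(L, d)
        if brute != w:
            raise AssertionError(
                f"closed form {w} disagrees with brute force {brute} for L={L}, d={d}"
            )
    return w


def make_variant(
    spacer: str, kind: str, rng: np.random.Generator
) -> tuple[str, DifferenceProfile]:
    """A planted off-target sequence of the given kind plus its expected profile.

    ``mm<k>`` substitutes a different base at each of the k equally spaced
    positions.  ``gap<g>`` deletes the base at each of the g equally spaced
    positions, yielding an RNA-bulge site of length ``len(spacer) - g``.
    ``ins<g>`` inserts an extra base (a DNA-bulge site of length
    ``len(spacer) + g``).  Positions are PAM-proximal (position 1 is the 3'
    base of the spacer).
    """
    L = len(spacer)
    if kind.startswith("mm"):
        k = int(kind[2:])
        positions = equally_spaced_positions(L, k) if k else ()
        chars = list(spacer)
        for p in positions:
            idx = L - p
            options = [b for b in _BASES if b != chars[idx]]
            chars[idx] = options[int(rng.integers(len(options)))]
        profile = DifferenceProfile.from_positions(positions)
        return "".join(chars), profile
    if kind.startswith("gap"):
        g = int(kind[3:])
        positions = equally_spaced_positions(L, g)
        chars = [c for i, c in enumerate(spacer) if (L - i) not in positions]
        profile = DifferenceProfile.from_positions((), [(p, RNA_BULGE) for p in positions])
        return "".join(chars), profile
    if kind.startswith("ins"):
        g = int(kind[3:])
        positions = equally_spaced_positions(L, g)
        chars = list(spacer)
        # Insert 5' of the base at each position so the extra base sits
        # between positions p and p+1 and is assigned position p+1.
        for p in sorted(positions):  # ascending position = descending index
            idx = L - p
            neighbours = {chars[idx]} | ({chars[idx - 1]} if idx > 0 else set())
            options = [b for b in _BASES if b not in neighbours]
            chars.insert(idx, options[int(rng.integers(len(options)))])
        profile = DifferenceProfile.from_positions(
            (), [(p + 1, DNA_BULGE) for p in positions]
        )
        return "".join(chars), profile
    raise ValueError(f"unknown variant kind {kind!r}")


def _draw_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A, C, G, T
    codes = rng.choice(4, size=length, p=probs)
    return "".join(_BASES[c] for c in codes)


def build_benchmark(
    spec: BenchmarkSpec, max_attempts: int = 100, chrom_name: str = "chr_synthetic"
) -> BenchmarkTruth:
    """Construct a benchmark genome with verified planted truth.

    The target and each variant (followed by an NGG PAM) overwrite the
    background at loci spaced >= 100 nt apart and >= 100 nt from the ends.
    The construction is rejected and redrawn unless an exhaustive search at
    the default budget confirms that (a) every planted variant is found with
    its expected mismatch/gap split, (b) each variant's edit distance to the
    spacer (checked with edlib) equals its expected total, and (c) no
    background window outside the planted inserts is as close to the spacer
    as any planted variant (total differences <= the largest planted total).
    Windows overlapping a planted insert through a shifted or alternative
    PAM ("satellites") are views of planted material, not background, and
    are tolerated, as are background windows near the edge of the search
    budget but farther away than every planted variant.
    """
    import edlib

    rng = np.random.default_rng(spec.rng_seed)
    spacer_len = 20
    for _attempt in range(max_attempts):
        background = _draw_sequence(rng, spec.background_length, spec.gc_content)
        spacer = spec.spacer or _draw_sequence(rng, spacer_len, spec.gc_content)
        variants = [make_variant(spacer, kind, rng) for kind in spec.variant_plan]
        # One locus for the target plus one per variant, evenly spread with
        # >= 100 nt margins.  Loci are PAM start coordinates.
        n_plant = 1 + len(variants)
        usable = spec.background_length - 200 - 25
        step = usable // n_plant
        pam_starts = [100 + spacer_len + 2 + i * step for i in range(n_plant)]
        seq = list(background)
        planted_ids: list[tuple[int, str]] = []  # (pam_start, planted_seq)
        for (pam_start, (vseq, _profile)) in zip(
            pam_starts, [(spacer, None)] + variants
        ):
            pam = _BASES[int(rng.integers(4))] + "GG"
            seq[pam_start - len(vseq) : pam_start + 3] = list(vseq + pam)
            planted_ids.append((pam_start, vseq))
        genome = Genome({chrom_name: "".join(seq)})
        chrom = genome[chrom_name]

        def window_site(pam_start: int) -> SpacerSite:
            return SpacerSite(
                interval=Interval(chrom_name, pam_start - spacer_len, pam_start, "+"),
                protospacer=chrom[pam_start - spacer_len : pam_start],
                pam=chrom[pam_start : pam_start + 3],
                pam_class=PAM_NGG,
                spacer_len=spacer_len,
            )

        target_site = window_site(pam_starts[0])
        planted = [
            PlantedVariant(kind, window_site(ps), profile, vseq)
            for kind, ps, (vseq, profile) in zip(
                spec.variant_plan, pam_starts[1:], variants
            )
        ]
        # Verify each variant against the bounded edit-distance oracle.
        if any(
            edlib.align(spacer, pv.planted_seq, mode="NW")["editDistance"]
            != pv.expected.total
            for pv in planted
        ):
            continue
        # Exhaustive search at the default budget: every planted site must be
        # found with its expected profile, and no background window may be as
        # close to the spacer as the planted variants are.
        params = SearchParams(pam_classes=frozenset({PAM_NGG, PAM_NAG}))
        sites = scan_pam_sites(genome, params.pam_classes, spacer_len)
        hits = search_offtargets(target_site, genome, sites, params)
        observed = {h.site.key(): h.profile for h in hits}
        expected_keys = {pv.site.key() for pv in planted}
        if not expected_keys <= set(observed):
            continue
        if any(
            observed[pv.site.key()].total != pv.expected.total
            or observed[pv.site.key()].n_mismatches != pv.expected.n_mismatches
            or observed[pv.site.key()].n_gaps != pv.expected.n_gaps
            for pv in planted
        ):
            continue
        max_planted_total = max(pv.expected.total for pv in planted)
        insert_spans = [
            (ps - len(vseq) - 3, ps + 6) for ps, vseq in planted_ids
        ]  # planted material plus a few flanking bases for shifted windows
        clean = True
        for h in hits:
            if h.site.key() in expected_keys or h.profile.total > max_planted_total:
                continue
            iv = h.site.interval
            if not any(iv.start < hi and lo < iv.end for lo, hi in insert_spans):
                clean = False
                break
        if not clean:
            continue
        return BenchmarkTruth(genome=genome, target_site=target_site, planted=planted)
    raise GenerationError(
        f"no acceptable background in {max_attempts} attempts; "
        "the benchmark spec is too permissive"
    )


def run_benchmark(truth: BenchmarkTruth, params: SearchParams) -> DetectionReport:
    """Search the target spacer and report which planted variants were found."""
    sites = scan_pam_sites(truth.genome, params.pam_classes, truth.target_site.spacer_len)
    hits = search_offtargets(truth.target_site, truth.genome, sites, params)
    observed = {h.site.key(): h.profile for h in hits}
    per_variant = []
    for pv in truth.planted:
        profile = observed.get(pv.site.key())
        per_variant.append(
            {
                "kind": pv.kind,
                "chrom": pv.site.interval.seq_name,
                "start": pv.site.interval.start,
                "end": pv.site.interval.end,
                "strand": pv.site.strand,
                "expected_total": pv.expected.total,
                "expected_mismatches": pv.expected.n_mismatches,
                "expected_gaps": pv.expected.n_gaps,
                "detected": profile is not None,
                "observed_total": None if profile is None else profile.total,
            }
        )
    return DetectionReport(params=params, per_variant=per_variant)
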