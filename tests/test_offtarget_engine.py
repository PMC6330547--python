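import edlib
import numpy as np
import pytest

from spacerscan.benchmark import BenchmarkSpec, build_benchmark
from spacerscan.offtarget_engine import (
    Alignment,
    DifferenceProfile,
    SearchParams,
    align_global,
    align_local,
    brute_force_oracle,
    diff_profile,
    search_offtargets,
    search_spacer,
)
from spacerscan.pam_scanner import PAM_NAG, PAM_NGG, scan_pam_sites
from spacerscan.sequence_io import Genome, reverse_complement

QUERY = "ACGTACGTACGTACGTACGT"
BOTH = frozenset({PAM_NGG, PAM_NAG})


def mutate(seq: str, positions: set[int]) -> str:
    """Substitute a different base at each PAM-proximal position (1 = 3' end)."""
    sub = {"A": "C", "C": "G", "G": "T", "T": "A"}
    chars = list(seq)
    for p in positions:
        idx = len(seq) - p
        chars[idx] = sub[chars[idx]]
    return "".join(chars)


def delete_at(seq: str, position: int) -> str:
    idx = len(seq) - position
    return seq[:idx] + seq[idx + 1 :]


def hit_keys(hits):
    return {(h.site.key(), h.profile.total) for h in hits}


class TestAlignGlobal:
    def test_identity(self):
        aln = align_global(QUERY, QUERY)
        assert aln.profile.total == 0
        assert aln.aligned_query == aln.aligned_subject == QUERY

    def test_single_deletion_recovered_as_rna_bulge(self):
        window = delete_at(QUERY, 10)
        assert edlib.align(QUERY, window, mode="NW")["editDistance"] == 1
        aln = align_global(QUERY, window)
        assert aln.profile.total == 1
        assert aln.profile.mismatch_positions == frozenset()
        assert aln.profile.gap_positions == frozenset({(10, "rna_bulge")})

    def test_two_mismatches_at_seed_boundary(self):
        window = mutate(QUERY, {7, 14})
        assert edlib.align(QUERY, window, mode="NW")["editDistance"] == 2
        aln = align_global(QUERY, window)
        assert aln.profile.total == 2
        assert aln.profile.mismatch_positions == frozenset({7, 14})
        assert aln.profile.seed10 == 1
        assert aln.profile.seed15 == 2

    def test_total_matches_edit_distance_on_random_pairs(self):
        # with unconstrained-enough gaps the minimal total equals edit distance
        rng = np.random.default_rng(0)
        for _ in range(50):
            q = "".join("ACGT"[c] for c in rng.integers(4, size=20))
            w = "".join("ACGT"[c] for c in rng.integers(4, size=20))
            ed = edlib.align(q, w, mode="NW")["editDistance"]
            total = align_global(q, w, max_gaps=2).profile.total
            if ed <= 2 or total <= 2:
                assert total == ed
            else:
                assert total >= ed

    def test_rows_ungap_to_inputs(self):
        window = delete_at(QUERY, 5)
        aln = align_global(QUERY, window)
        assert aln.aligned_query.replace("-", "") == QUERY
        assert aln.aligned_subject.replace("-", "") == window
        assert "--" not in [
            a + b for a, b in zip(aln.aligned_query, aln.aligned_subject)
        ]

    def test_length_difference_beyond_gap_budget_rejected(self):
        with pytest.raises(ValueError, match="max_gaps"):
            align_global(QUERY, QUERY[:16], max_gaps=2)

    def test_tie_break_prefers_fewest_seed_differences(self):
        # deleting one base of a homopolymer run straddling the 10-nt seed
        # boundary: the bulge can sit at position 10 or 11; the engine must
        # take the least seed-disrupted reading (position 11).
        q = "ACGTACGTC" + "AA" + "GTACGTACG"  # positions 10 and 11 are both A
        window = q[:9] + q[10:]  # delete one of the two A's
        aln = align_global(q, window)
        assert aln.profile.total == 1
        assert aln.profile.seed10 == 0


class TestAlignLocal:
    def test_identity_covers_full_length(self):
        aln = align_local(QUERY, QUERY)
        assert aln.aligned_query == QUERY
        assert aln.profile.total == 0

    def test_central_deletion_splits_into_sub_segments(self):
        window = delete_at(QUERY, 10)
        aln = align_local(QUERY, window)
        matches = sum(a == b for a, b in zip(aln.aligned_query, aln.aligned_subject))
        assert matches >= 10

    def test_no_shared_4mer_gives_short_segments(self):
        window = "A" * 20  # QUERY contains no AA, so no shared 4-mer
        aln = align_local(QUERY, window)
        run = best = 0
        for a, b in zip(aln.aligned_query, aln.aligned_subject):
            run = run + 1 if a == b else 0
            best = max(best, run)
        assert best < 4


class TestDiffProfile:
    def test_empty_profile(self):
        aln = Alignment(QUERY, QUERY, DifferenceProfile.from_positions(()))
        p = diff_profile(aln)
        assert (p.total, p.seed10, p.seed15) == (0, 0, 0)

    @pytest.mark.parametrize(
        "positions,seed10,seed15",
        [({12, 16, 19}, 0, 1), ({7, 14}, 1, 2), ({1, 10, 15}, 2, 3)],
    )
    def test_seed_counting(self, positions, seed10, seed15):
        window = mutate(QUERY, positions)
        p = diff_profile(Alignment(QUERY, window, DifferenceProfile.from_positions(())))
        assert p.mismatch_positions == frozenset(positions)
        assert (p.total, p.seed10, p.seed15) == (len(positions), seed10, seed15)

    def test_profile_invariants_enforced(self):
        with pytest.raises(ValueError):
            DifferenceProfile(frozenset({1}), frozenset(), total=2, seed10=1, seed15=1)
        with pytest.raises(ValueError):
            DifferenceProfile(frozenset({1}), frozenset(), total=1, seed10=1, seed15=0)


class TestSearch:
    def test_self_exclusion_on_lone_site(self):
        genome = Genome({"c": "T" * 30 + QUERY + "TGG" + "T" * 30})
        sites = scan_pam_sites(genome, BOTH)
        query_site = [s for s in sites if s.protospacer == QUERY][0]
        hits = search_offtargets(query_site, genome, sites, SearchParams(pam_classes=BOTH))
        assert hits == []

    def test_exact_duplicate_reported_as_zero_difference_hit(self):
        genome = Genome(
            {"c": "T" * 30 + QUERY + "TGG" + "T" * 50 + QUERY + "CGG" + "T" * 30}
        )
        sites = scan_pam_sites(genome, BOTH)
        query_site = [s for s in sites if s.protospacer == QUERY][0]
        hits = search_offtargets(query_site, genome, sites, SearchParams(pam_classes=BOTH))
        zero = [h for h in hits if h.profile.total == 0]
        assert len(zero) == 1

    def test_query_site_must_come_from_genome(self):
        genome = Genome({"c": "T" * 30 + QUERY + "TGG" + "T" * 30})
        other = Genome({"c": "A" * 33 + QUERY + "TGG" + "A" * 30})
        sites = scan_pam_sites(genome, BOTH)
        foreign = scan_pam_sites(other, BOTH)
        foreign_site = [s for s in foreign if s.protospacer == QUERY][0]
        with pytest.raises(ValueError):
            search_offtargets(foreign_site, genome, sites, SearchParams(pam_classes=BOTH))

    def test_window_containing_n_is_not_searched(self):
        variant = mutate(QUERY, {5})
        with_n = variant[:3] + "N" + variant[4:]
        genome = Genome({"c": "T" * 30 + with_n + "TGG" + "T" * 30})
        sites = scan_pam_sites(genome, BOTH)
        assert sites == []
        assert search_spacer(QUERY, genome, sites, SearchParams(pam_classes=BOTH)) == []

    def test_monotonicity_in_budget(self):
        truth = build_benchmark(BenchmarkSpec(background_length=3000, rng_seed=13))
        genome, q = truth.genome, truth.target_site
        sites = scan_pam_sites(genome, BOTH)
        previous: set = set()
        for mm, gaps in [(0, 0), (1, 0), (2, 1), (3, 1), (4, 2)]:
            params = SearchParams(max_mismatches=mm, max_gaps=gaps, pam_classes=BOTH)
            current = {h.site.key() for h in search_offtargets(q, genome, sites, params)}
            assert previous <= current
            previous = current

    def test_strand_symmetry_of_hits(self):
        truth = build_benchmark(BenchmarkSpec(background_length=3000, rng_seed=17))
        genome, q = truth.genome, truth.target_site
        name = q.interval.seq_name
        L = genome.length(name)
        mirrored = Genome({name: reverse_complement(genome[name])})
        params = SearchParams(pam_classes=BOTH)
        fwd_hits = search_offtargets(q, genome, scan_pam_sites(genome, BOTH), params)
        m_sites = scan_pam_sites(mirrored, BOTH)
        flip = {"+": "-", "-": "+"}
        mirror_q = [
            s
            for s in m_sites
            if s.interval.start == L - q.interval.end and s.strand == flip[q.strand]
        ][0]
        rev_hits = search_offtargets(mirror_q, mirrored, m_sites, params)
        fwd = {
            (L - h.site.interval.end, flip[h.site.strand], h.profile.total)
            for h in fwd_hits
        }
        rev = {(h.site.interval.start, h.site.strand, h.profile.total) for h in rev_hits}
        assert fwd == rev

    def test_seeded_subset_of_exhaustive(self):
        truth = build_benchmark(BenchmarkSpec(background_length=3000, rng_seed=23))
        genome, q = truth.genome, truth.target_site
        sites = scan_pam_sites(genome, BOTH)
        exhaustive = hit_keys(
            search_offtargets(q, genome, sites, SearchParams(pam_classes=BOTH))
        )
        for w in (3, 5, 7, 10, 15):
            seeded = hit_keys(
                search_offtargets(
                    q, genome, sites,
                    SearchParams(mode="seeded", word_size=w, pam_classes=BOTH),
                )
            )
            assert seeded <= exhaustive

    def test_hits_respect_budget_and_profile_invariants(self):
        truth = build_benchmark(BenchmarkSpec(background_length=3000, rng_seed=29))
        genome, q = truth.genome, truth.target_site
        sites = scan_pam_sites(genome, BOTH)
        params = SearchParams(pam_classes=BOTH)
        for h in search_offtargets(q, genome, sites, params):
            p = h.profile
            assert p.n_mismatches <= params.max_mismatches
            assert p.n_gaps <= params.max_gaps
            assert 0 <= p.seed10 <= p.seed15 <= p.total
            assert h.site.pam_class in params.pam_classes


class TestOracleEquivalence:
    def test_engine_matches_oracle_on_small_genomes(self):
        for seed in (101, 102):
            truth = build_benchmark(BenchmarkSpec(background_length=10_000, rng_seed=seed))
            genome, q = truth.genome, truth.target_site
            params = SearchParams(pam_classes=BOTH)
            sites = scan_pam_sites(genome, BOTH)
            engine = hit_keys(search_offtargets(q, genome, sites, params))
            oracle = {
                ((o.seq_name, o.start, o.end, o.strand), o.total)
                for o in brute_force_oracle(q.protospacer, genome, params, exclude=q.key())
            }
            assert engine == oracle

    def test_oracle_on_empty_genome(self):
        genome = Genome({"c": "T" * 100})
        assert brute_force_oracle(QUERY, genome, SearchParams(pam_classes=BOTH)) == []

    def test_oracle_finds_exact_duplicate(self):
        genome = Genome({"c": "T" * 30 + QUERY + "TGG" + "T" * 30})
        hits = brute_force_oracle(QUERY, genome, SearchParams(pam_classes=BOTH))
        assert [(h.total, h.pam_class) for h in hits] == [(0, PAM_NGG)]
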