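"""Conservation scoring, the Chebyshev outlier model, and the scUMC calls."""
import math

import numpy as np
import pytest

from scumc import (
    CandidateUMC,
    GenomicRegion,
    RegionIndex,
    build_candidates,
    call_conserved_umrs,
    call_credible_umcs,
    call_nonconserved_umcs,
    chebyshev_p,
    conservation_score,
    fit_chebyshev,
    merge_credible,
    nonredundant_umrs,
    run_scumc_pipeline,
)
from conftest import make_methylome


def cand(pos, presence, chrom="chr1"):
    vec = np.asarray(presence, dtype=np.uint8)
    return CandidateUMC(chrom, pos, vec, len(vec))


class TestConservationScore:
    @pytest.mark.parametrize(
        "n_present,n,expected",
        [(31, 31, 100.0), (0, 31, 0.0), (10, 31, 1000.0 / 31), (1, 4, 25.0)],
    )
    def test_exact_percentage(self, n_present, n, expected):
        presence = [1] * n_present + [0] * (n - n_present)
        assert conservation_score(presence, n) == pytest.approx(expected, abs=1e-12)

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError):
            conservation_score([], 0)


class TestChebyshev:
    def test_tail_bound_values(self):
        assert chebyshev_p(4.5) == pytest.approx(1 / 4.5**2)
        assert chebyshev_p(1) == 1.0
        assert chebyshev_p(10) == pytest.approx(0.01)

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            chebyshev_p(0)

    def test_fit_hand_example(self):
        # scores with population mean 5 and sd 1; p = 0.04 -> k = 5
        scores = [4.0, 6.0, 4.0, 6.0]
        model = fit_chebyshev(scores, p=0.04, n_samples=20)
        assert (model.m, model.v, model.k) == (5.0, 1.0, 5.0)
        assert model.threshold == pytest.approx(10.0)
        assert model.n_min == 2  # ceil(10 * 20 / 100)

    def test_limit_cases(self):
        model = fit_chebyshev([0.0, 10.0], p=1.0, n_samples=10)
        assert model.k == 1.0
        assert model.threshold == pytest.approx(model.m + model.v)
        assert fit_chebyshev([0.0, 10.0], p=0.01, n_samples=10).k == 10.0

    def test_degenerate_scores_rejected(self):
        with pytest.raises(ValueError):
            fit_chebyshev([5.0, 5.0, 5.0], p=0.01, n_samples=10)

    def test_bad_p_rejected(self):
        with pytest.raises(ValueError):
            fit_chebyshev([1.0, 2.0], p=0.0, n_samples=10)


def four_sample_methylomes():
    """Four samples over five CpGs at 1000..1200 step 50.

    CpG 1000 is a UMC in sample 0 only; 1100 in samples 0-2; all other
    sites are highly methylated.
    """
    base = [0.8, 0.9, 0.85, 0.9, 0.8]
    rows = []
    for i in range(4):
        ratios = list(base)
        if i == 0:
            ratios[0] = 0.05
        if i <= 2:
            ratios[2] = 0.02
        rows.append(make_methylome(ratios, sample_id=f"S{i}"))
    return rows


class TestBuildCandidates:
    def test_presence_and_score(self):
        cands = build_candidates(four_sample_methylomes(), [])
        assert [(c.pos, c.n_present) for c in cands] == [(1000, 1), (1100, 3)]
        assert cands[0].score == 25.0

    def test_umr_exclusion(self):
        umrs = [[GenomicRegion("chr1", 1090, 1110)]]
        cands = build_candidates(four_sample_methylomes(), umrs)
        assert [c.pos for c in cands] == [1000]

    def test_snp_exclusion(self):
        cands = build_candidates(
            four_sample_methylomes(), [], snp_positions={("chr1", 1000)}
        )
        assert [c.pos for c in cands] == [1100]

    def test_duplicate_sample_id_rejected(self):
        ms = four_sample_methylomes()
        ms[1] = make_methylome([0.5] * 5, sample_id="S0")
        with pytest.raises(ValueError, match="duplicate"):
            build_candidates(ms, [])

    def test_callable_only_uses_per_cpg_denominator(self):
        ms = four_sample_methylomes()
        # sample 3 loses coverage at CpG 1000: denominator drops to 3
        df = ms[3].records.copy()
        df.loc[df["pos"] == 1000, "coverage"] = 2
        ms[3] = type(ms[3])("S3", df)
        cands = build_candidates(ms, [], callable_only=True)
        c0 = next(c for c in cands if c.pos == 1000)
        assert c0.denominator == 3
        assert c0.score == pytest.approx(100.0 / 3)


class TestCredibleAndMerge:
    def model(self, n_min=2, n_samples=4, m=5.0, v=1.0):
        from scumc import ChebyshevModel

        return ChebyshevModel(
            m=m, v=v, p=0.04, k=5.0, threshold=m + 5 * v,
            n_min=n_min, n_samples=n_samples,
        )

    def test_boundary_count_is_credible(self):
        cands = [cand(100, [1, 1, 0, 0]), cand(200, [1, 0, 0, 0])]
        got = call_credible_umcs(cands, self.model(n_min=2))
        assert [c.pos for c in got] == [100]

    def test_score_and_count_criteria_agree(self):
        # a background of singletons with a few high outliers keeps the
        # score threshold attainable, where the two criteria must coincide
        rng = np.random.default_rng(0)
        n = 20
        cands = []
        for i, pos in enumerate(range(0, 50_000, 25)):
            k = int(rng.choice([1, 1, 1, 1, 2]))
            if i % 200 == 0:
                k = int(rng.integers(10, n + 1))
            vec = np.zeros(n, dtype=np.uint8)
            vec[rng.choice(n, size=k, replace=False)] = 1
            cands.append(CandidateUMC("chr1", pos, vec, n))
        model = fit_chebyshev([c.score for c in cands], p=0.01, n_samples=n)
        assert model.threshold <= 100.0
        by_count = {c.pos for c in call_credible_umcs(cands, model)}
        by_score = {c.pos for c in cands if c.score >= model.threshold - 1e-9}
        assert by_count == by_score

    def test_decreasing_p_never_grows_the_credible_set(self):
        rng = np.random.default_rng(1)
        n = 16
        cands = []
        for pos in range(0, 3000, 10):
            k = int(rng.integers(1, n + 1)) if rng.random() < 0.1 else 1
            vec = np.zeros(n, dtype=np.uint8)
            vec[rng.choice(n, size=k, replace=False)] = 1
            cands.append(CandidateUMC("chr1", pos, vec, n))
        scores = [c.score for c in cands]
        prev = None
        for p in (1.0, 0.25, 0.05, 0.01):
            model = fit_chebyshev(scores, p=p, n_samples=n)
            cur = {c.pos for c in call_credible_umcs(cands, model)}
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_merge_examples(self):
        got = merge_credible(
            [cand(1000, [1]), cand(1200, [1]), cand(1600, [1])], merge_gap=300
        )
        assert [(r.start, r.end, r.attrs["n_members"]) for r in got] == [
            (1000, 1202, 2),
            (1600, 1602, 1),
        ]

    def test_merge_single_position(self):
        (r,) = merge_credible([cand(5000, [1])])
        assert (r.start, r.end) == (5000, 5002)

    def test_merge_gap_boundary_is_inclusive(self):
        (r,) = merge_credible([cand(0, [1]), cand(300, [1])], merge_gap=300)
        assert (r.start, r.end, r.attrs["n_members"]) == (0, 302, 2)

    def test_merge_never_bridges_an_excluded_umr(self):
        excl = RegionIndex([GenomicRegion("chr1", 1050, 1150)])
        got = merge_credible(
            [cand(1000, [1]), cand(1200, [1])], merge_gap=300, excluded=excl
        )
        assert [(r.start, r.end) for r in got] == [(1000, 1002), (1200, 1202)]


class TestNonredundantUmrs:
    def test_overlap_merges(self):
        got = nonredundant_umrs(
            [[GenomicRegion("chr1", 10, 50)], [GenomicRegion("chr1", 40, 90)]]
        )
        assert [(r.start, r.end) for r in got] == [(10, 90)]

    def test_disjoint_kept(self):
        got = nonredundant_umrs(
            [[GenomicRegion("chr1", 10, 20), GenomicRegion("chr1", 30, 40)]]
        )
        assert [(r.start, r.end) for r in got] == [(10, 20), (30, 40)]

    def test_book_ended_merge(self):
        got = nonredundant_umrs(
            [[GenomicRegion("chr1", 10, 20)], [GenomicRegion("chr1", 20, 30)]]
        )
        assert [(r.start, r.end) for r in got] == [(10, 30)]

    def test_matches_coverage_sweep_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(1, 400))
            starts = rng.integers(0, 5000, n)
            ends = starts + rng.integers(1, 200, n)
            regs = [
                GenomicRegion("chr1", int(s), int(e))
                for s, e in zip(starts, ends)
            ]
            got = [(r.start, r.end) for r in nonredundant_umrs([regs])]
            # oracle: paint base pairs, read off maximal painted stretches
            paint = np.zeros(int(ends.max()) + 2, dtype=bool)
            for s, e in zip(starts, ends):
                paint[s:e] = True
            edges = np.flatnonzero(np.diff(np.r_[False, paint, False]))
            want = list(zip(edges[::2].tolist(), edges[1::2].tolist()))
            assert got == want


class TestConservedUmrs:
    def test_boundary_hit_qualifies(self):
        ms = four_sample_methylomes()
        model = TestCredibleAndMerge().model(n_min=3, n_samples=4)
        regions = [
            GenomicRegion("chr1", 1080, 1120),  # holds CpG 1100 (3 samples)
            GenomicRegion("chr1", 990, 1010),  # holds CpG 1000 (1 sample)
        ]
        got = call_conserved_umrs(regions, ms, model)
        assert [(r.start, r.attrs["max_samples"]) for r in got] == [(1080, 3)]

    def test_all_cpgs_one_short_fails(self):
        ms = four_sample_methylomes()
        model = TestCredibleAndMerge().model(n_min=4, n_samples=4)
        got = call_conserved_umrs([GenomicRegion("chr1", 990, 1210)], ms, model)
        assert got == []


class TestNonconserved:
    def test_partition_of_candidates(self):
        rng = np.random.default_rng(2)
        n = 12
        cands = []
        for pos in range(0, 2000, 10):
            k = int(rng.integers(1, n + 1)) if rng.random() < 0.15 else 1
            vec = np.zeros(n, dtype=np.uint8)
            vec[rng.choice(n, size=k, replace=False)] = 1
            cands.append(CandidateUMC("chr1", pos, vec, n))
        from scumc import fit_chebyshev

        model = fit_chebyshev([c.score for c in cands], p=0.01, n_samples=n)
        credible = {c.pos for c in call_credible_umcs(cands, model)}
        noncons = {c.pos for c in call_nonconserved_umcs(cands, model)}
        assert credible.isdisjoint(noncons)
        assert credible | noncons <= {c.pos for c in cands}
        lenient = model.m + math.sqrt(1 / 0.95) * model.v
        want = {
            c.pos
            for c in cands
            if c.score < lenient and c.n_present < model.n_min
        }
        assert noncons == want

    def test_mean_scoring_candidate_included(self):
        model = TestCredibleAndMerge().model(n_min=3, n_samples=4, m=25.0, v=10.0)
        c = cand(10, [1, 0, 0, 0])  # score 25 == m, below any lenient cutoff
        assert call_nonconserved_umcs([c], model) == [c]

    def test_bad_lenient_p_rejected(self):
        model = TestCredibleAndMerge().model()
        with pytest.raises(ValueError):
            call_nonconserved_umcs([], model, lenient_p=0.0)


class TestPipelineInvariance:
    def test_sample_order_does_not_change_calls(self):
        ms = four_sample_methylomes()
        # add enough score diversity for a model fit
        a = run_scumc_pipeline(ms, p=1.0)
        b = run_scumc_pipeline(ms[::-1], p=1.0)
        assert [r.key() for r in a.scumc_regions] == [
            r.key() for r in b.scumc_regions
        ]
        assert a.model == b.model
        assert [c.pos for c in a.nonconserved] == [c.pos for c in b.nonconserved]
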