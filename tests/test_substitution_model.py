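import numpy as np
import pytest

from dnactx import (ContextSpec, Genome, VariantRecord, calibration_curve,
                    compute_z, cumulative_mutability, fit, fit_alpha,
                    fit_simple, mutability_track, read_alpha_tsv,
                    site_mutability, write_alpha_tsv)
from dnactx.substitution_model import AlphaMatrix
from dnactx.synthetic_data import sample_genome, sample_variants, GeneratorSpec
from conftest import random_genome


class _ConstantModel:
    """Genome model scoring every interior site with a fixed distribution."""

    def __init__(self, p, margin=1):
        self.p = np.asarray(p, float)
        self.margin = margin

    def evaluate_record(self, genome, chrom, leave_one_out=False):
        n = genome.length(chrom)
        sites = np.arange(self.margin, n - self.margin)
        keep = genome.codes(chrom)[sites] != 4
        sites = sites[keep]
        return sites, np.tile(self.p, (len(sites), 1))


def _alpha_k0(values):
    """k_hat=0 alpha matrix from a (4,4) array (diagonal ignored)."""
    a = np.asarray(values, float).copy()
    a[np.arange(4), np.arange(4)] = np.nan
    return AlphaMatrix(0, np.array([0]), a[None], np.full((1, 4, 4), np.nan),
                       np.zeros((1, 4, 4), np.int64), np.zeros((1, 4), np.int64))


class TestFitSimple:
    def test_hand_counted_fraction(self):
        # AAAAATTTTT is its own revcomp: n(A) = 10 on the two strands;
        # two A->G variants give p_simple(A->G) = 2/10
        g = Genome([("c1", "AAAAATTTTT")])
        variants = [VariantRecord("c1", 0, "A", "G"),
                    VariantRecord("c1", 1, "A", "G")]
        m = fit_simple(variants, g, k_hat=0)
        assert m.n_ref[0, 0] == 10
        assert m.p("", "A", "G") == pytest.approx(0.2)
        # strand symmetrization: the same events read as T->C
        assert m.p("", "T", "C") == pytest.approx(0.2)

    def test_no_variants_all_zero(self, rng):
        g = random_genome(rng, 500)
        m = fit_simple([], g, k_hat=1)
        p = m.p_simple
        assert np.nansum(p) == 0.0

    def test_k0_degenerate_table_shape(self, rng):
        g = random_genome(rng, 500)
        m = fit_simple([], g, k_hat=0)
        assert m.n_ref.shape == (1, 4) and m.n_mut.shape == (1, 4, 4)

    def test_ref_mismatch_is_error(self):
        g = Genome([("c1", "CCCCC")])
        with pytest.raises(ValueError, match="disagrees"):
            fit_simple([VariantRecord("c1", 2, "A", "G")], g, k_hat=0)


class TestComputeZ:
    def test_mean_of_constant_model(self, rng):
        g = random_genome(rng, 400)
        # complement-symmetric constant so both strand readings agree
        z = compute_z(_ConstantModel([0.3, 0.2, 0.2, 0.3]), g, k_hat=0)
        assert z.z[0, :, 0] == pytest.approx(np.full(4, 0.3))
        assert z.z[0, :, 1] == pytest.approx(np.full(4, 0.2))

    def test_two_site_mean(self):
        # one strand reading with P(C)=0.2 and its mirror with P(G)=0.2;
        # restrict to ref A so only forward readings hit (0, A)
        class _TwoSites:
            def evaluate_record(self, genome, chrom, leave_one_out=False):
                return (np.array([1, 2]),
                        np.array([[0.4, 0.2, 0.1, 0.3],
                                  [0.2, 0.4, 0.1, 0.3]]))

        g = Genome([("c1", "AAAA")])
        z = compute_z(_TwoSites(), g, k_hat=0)
        # both readings have ref A: z(A -> C) = (0.2 + 0.4) / 2
        assert z.z[0, 0, 1] == pytest.approx(0.3)

    def test_rows_sum_to_one(self, rng):
        g = random_genome(rng, 2000)
        model = fit(ContextSpec("central", 1, 1, 100.0), g)
        z = compute_z(model, g, k_hat=1)
        sums = np.nansum(z.z, axis=2)
        present = z.n_sites > 0
        assert np.allclose(sums[present], 1.0, atol=1e-9)


class TestFitAlpha:
    def test_division(self, rng):
        g = Genome([("c1", "AAAAATTTTT")])
        variants = [VariantRecord("c1", 0, "A", "G"),
                    VariantRecord("c1", 1, "A", "G")]
        simple = fit_simple(variants, g, k_hat=0)   # p(A->G) = 0.2
        z = compute_z(_ConstantModel([0.1, 0.1, 0.4, 0.4]), g, k_hat=0)
        amat = fit_alpha(simple, z)
        # symmetrized z(A->G) = (0.4 + 0.1)/2 = 0.25 -> alpha = 0.2/0.25
        assert amat.value("", "A", "G") == pytest.approx(0.8)

    def test_zero_p_simple_gives_zero_alpha(self, rng):
        g = random_genome(rng, 400)
        simple = fit_simple([], g, k_hat=0)
        z = compute_z(_ConstantModel([0.25] * 4), g, k_hat=0)
        amat = fit_alpha(simple, z)
        off = ~np.eye(4, dtype=bool)
        assert np.all(amat.alpha[0][off] == 0.0)

    def test_strand_symmetry_of_estimates(self):
        rng = np.random.default_rng(31)
        g = sample_genome(GeneratorSpec("iid", 0, np.full((1, 4), 0.25),
                                        60_000, seed=3))
        model = fit(ContextSpec("markov", 1, 1, 100.0), g)
        truth = _alpha_k0(rng.uniform(0.02, 0.1, (4, 4)))
        # symmetrize the truth so sampling itself is strand-symmetric
        sym = (truth.alpha[0] + truth.alpha[0][::-1, ::-1]) / 2
        variants = sample_variants(g, _alpha_k0(sym), model, seed=4)
        simple = fit_simple(variants, g, k_hat=1)
        amat = fit_alpha(simple, compute_z(model, g, k_hat=1))
        # alpha(s,a,b) == alpha(revcomp(s), comp a, comp b) by construction
        assert amat.value("AC", "A", "G") == pytest.approx(
            amat.value("GT", "T", "C"))
        assert amat.value("CG", "C", "T") == pytest.approx(
            amat.value("CG", "G", "A"))

    def test_khat_mismatch_rejected(self, rng):
        g = random_genome(rng, 400)
        simple = fit_simple([], g, k_hat=1)
        z = compute_z(_ConstantModel([0.25] * 4), g, k_hat=0)
        with pytest.raises(ValueError):
            fit_alpha(simple, z)


class TestMutability:
    def test_closed_form(self, rng):
        # alpha 0.1 against P(b)=0.2 gives mu 0.02 per alt;
        # three alts -> total 1 - exp(-0.06)
        g = Genome([("c1", "ACGTACGTAC")])
        amat = _alpha_k0(np.full((4, 4), 0.1))
        model = _ConstantModel([0.2, 0.2, 0.2, 0.4])
        track = mutability_track(amat, model, g)
        row = track[track["pos"] == 1].iloc[0]      # ref C
        assert row["muA"] == pytest.approx(0.02)
        assert row["muC"] == 0.0
        assert row["muT"] == pytest.approx(0.04)
        expected_total = 1 - np.exp(-(0.02 + 0.02 + 0.04))
        assert row["total"] == pytest.approx(expected_total)
        assert row["total"] <= 0.02 + 0.02 + 0.04

    def test_zero_alpha_zero_mutability(self, rng):
        g = random_genome(rng, 200)
        amat = _alpha_k0(np.zeros((4, 4)))
        track = mutability_track(amat, _ConstantModel([0.25] * 4), g)
        assert np.all(track["total"] == 0.0)

    def test_exact_reduction_when_contexts_match(self):
        # with s_hat = s and the genome model being the central conditional
        # distribution, mu equals P_simple at machine precision
        rng = np.random.default_rng(8)
        tab = rng.dirichlet(np.ones(4) * 4, size=4)
        g = sample_genome(GeneratorSpec("markov", 1, tab, 20_000, seed=5),
                          name="c1")
        cm = fit(ContextSpec("central", 1, 1, 0.0), g)
        truth = _alpha_k0((rng.uniform(0.02, 0.12, (4, 4)) +
                           rng.uniform(0.02, 0.12, (4, 4))) / 2)
        variants = sample_variants(g, truth, cm, seed=9)
        simple = fit_simple(variants, g, 1)
        amat = fit_alpha(simple, compute_z(cm, g, 1))
        track = mutability_track(amat, cm, g)
        ps = simple.p_simple
        ctx_idx = {int(c): i for i, c in enumerate(simple.contexts)}
        codes = g.codes("c1")
        for _, r in track.sample(200, random_state=0).iterrows():
            pos, a = int(r["pos"]), "ACGT".index(r["ref"])
            i = ctx_idx[int(codes[pos - 1]) * 4 + int(codes[pos + 1])]
            for b, base in enumerate("ACGT"):
                if b != a and np.isfinite(ps[i, a, b]):
                    assert abs(r[f"mu{base}"] - ps[i, a, b]) < 1e-12

    def test_absent_alpha_scores_zero_with_warning(self, rng, caplog):
        import logging
        g = random_genome(rng, 200)
        amat = _alpha_k0(np.full((4, 4), np.nan))
        with caplog.at_level(logging.WARNING):
            track = mutability_track(amat, _ConstantModel([0.25] * 4), g)
        assert np.all(track["total"] == 0.0)
        assert "absent alpha" in caplog.text

    def test_site_mutability_matches_track(self, rng):
        g = random_genome(rng, 100)
        amat = _alpha_k0(np.full((4, 4), 0.05))
        model = _ConstantModel([0.25] * 4)
        entry = site_mutability(amat, model, g, "c1", 10)
        track = mutability_track(amat, model, g)
        row = track[track["pos"] == 10].iloc[0]
        assert entry["total"] == pytest.approx(row["total"])

    def test_total_in_unit_interval_and_monotone(self, rng):
        g = random_genome(rng, 500)
        small = mutability_track(_alpha_k0(np.full((4, 4), 0.05)),
                                 _ConstantModel([0.25] * 4), g)
        large = mutability_track(_alpha_k0(np.full((4, 4), 0.10)),
                                 _ConstantModel([0.25] * 4), g)
        assert np.all((small["total"] >= 0) & (small["total"] < 1))
        assert np.all(large["total"].to_numpy() >=
                      small["total"].to_numpy() - 1e-15)


class TestCalibration:
    def test_no_variants(self, rng):
        g = random_genome(rng, 300)
        track = mutability_track(_alpha_k0(np.full((4, 4), 0.05)),
                                 _ConstantModel([0.25] * 4), g)
        curve = calibration_curve(track, [], bin_width=0.01)
        occupied = curve[curve["n_sites"] > 0]
        assert np.all(occupied["fraction"] == 0.0)

    def test_all_sites_variant(self, rng):
        g = random_genome(rng, 300)
        track = mutability_track(_alpha_k0(np.full((4, 4), 0.05)),
                                 _ConstantModel([0.25] * 4), g)
        variants = [VariantRecord(c, int(p), r, "ACGT"[("ACGT".index(r) + 1) % 4])
                    for c, p, r in zip(track["chrom"], track["pos"], track["ref"])]
        curve = calibration_curve(track, variants, bin_width=0.01)
        occupied = curve[curve["n_sites"] > 0]
        assert np.all(occupied["fraction"] == 1.0)

    def test_smooth_column_optional(self, rng):
        g = random_genome(rng, 300)
        track = mutability_track(_alpha_k0(np.full((4, 4), 0.05)),
                                 _ConstantModel([0.25] * 4), g)
        assert "fraction_smooth" not in calibration_curve(track, []).columns
        assert "fraction_smooth" in calibration_curve(
            track, [], smooth=True).columns


class TestCumulative:
    def test_step_function_for_constant_track(self, rng):
        g = random_genome(rng, 300)
        track = mutability_track(_alpha_k0(np.full((4, 4), 0.06)),
                                 _ConstantModel([0.25] * 4), g)
        value = track["total"].iloc[0]
        cdf = cumulative_mutability(track, grid=np.array([0.0, value / 2,
                                                          value, value * 2]))
        assert list(cdf["cum_fraction"]) == [0.0, 0.0, 1.0, 1.0]

    def test_reaches_one_and_nondecreasing(self, rng):
        g = random_genome(rng, 500)
        rng2 = np.random.default_rng(0)
        a = rng2.uniform(0.01, 0.1, (4, 4))
        track = mutability_track(_alpha_k0(a), _ConstantModel([0.25] * 4), g)
        cdf = cumulative_mutability(track, grid=50)
        assert cdf["cum_fraction"].iloc[-1] == 1.0
        assert np.all(np.diff(cdf["cum_fraction"]) >= 0)

    def test_variant_sites_stochastically_more_mutable(self):
        rng = np.random.default_rng(77)
        g = sample_genome(GeneratorSpec("iid", 0, np.full((1, 4), 0.25),
                                        50_000, seed=6))
        model = fit(ContextSpec("markov", 1, 1, 100.0), g)
        a = rng.uniform(0.01, 0.15, (4, 4))
        amat = _alpha_k0((a + a[::-1, ::-1]) / 2)
        variants = sample_variants(g, amat, model, seed=8)
        track = mutability_track(amat, model, g)
        grid = np.linspace(0, float(track["total"].max()), 30)
        all_cdf = cumulative_mutability(track, grid=grid)
        var_cdf = cumulative_mutability(
            track, subset={(v.chrom, v.pos) for v in variants}, grid=grid)
        # variants sampled proportionally to mutability: their CDF lies below
        mid = slice(5, 25)
        assert np.mean(var_cdf["cum_fraction"].to_numpy()[mid] <=
                       all_cdf["cum_fraction"].to_numpy()[mid] + 1e-9) > 0.9


class TestCpG:
    def test_ct_enrichment_at_cpg_sites(self):
        # alpha with C->T boosted when the right neighbour is G must produce
        # variant sets enriched for C->T at CpG dinucleotides
        rng = np.random.default_rng(13)
        g = sample_genome(GeneratorSpec("iid", 0, np.full((1, 4), 0.25),
                                        80_000, seed=14))
        model = fit(ContextSpec("markov", 1, 1, 100.0), g)
        base = np.full((4, 4), 0.02)
        alpha = np.tile(base, (16, 1, 1))
        for left in range(4):
            ctx_cg = left * 4 + 2            # context x_(i-1)=left, x_(i+1)=G
            alpha[ctx_cg, 1, 3] = 0.5        # C->T boosted
            ctx_rc = 1 * 4 + (3 - left)      # mirrored context C_?
            alpha[ctx_rc, 2, 0] = 0.5        # G->A boosted (strand mirror)
        amat = AlphaMatrix(1, np.arange(16), alpha,
                           np.full((16, 4, 4), np.nan),
                           np.zeros((16, 4, 4), np.int64),
                           np.zeros((16, 4), np.int64))
        variants = sample_variants(g, amat, model, seed=15)
        codes = g.codes("chr1")
        ct_cpg = ct_other = n_cpg = n_other = 0
        for pos in range(1, len(codes) - 1):
            if codes[pos] != 1:
                continue
            is_cpg = codes[pos + 1] == 2
            if is_cpg:
                n_cpg += 1
            else:
                n_other += 1
        for v in variants:
            if v.ref == "C" and v.alt == "T":
                if codes[v.pos + 1] == 2:
                    ct_cpg += 1
                else:
                    ct_other += 1
        rate_cpg = ct_cpg / n_cpg
        rate_other = ct_other / n_other
        assert rate_cpg > 5 * rate_other


class TestAlphaSerialization:
    def test_tsv_round_trip(self, rng, tmp_path):
        g = random_genome(rng, 3000)
        model = fit(ContextSpec("central", 1, 1, 100.0), g)
        variants = sample_variants(g, _alpha_k0(np.full((4, 4), 0.08)),
                                   model, seed=21)
        simple = fit_simple(variants, g, k_hat=1)
        amat = fit_alpha(simple, compute_z(model, g, k_hat=1))
        p = tmp_path / "alpha.tsv"
        write_alpha_tsv(amat, p)
        back = read_alpha_tsv(p)
        assert back.k_hat == amat.k_hat
        assert np.array_equal(back.contexts, amat.contexts)
        both = np.isfinite(amat.alpha) & np.isfinite(back.alpha)
        assert np.allclose(back.alpha[both], amat.alpha[both], rtol=1e-9)
        assert np.array_equal(back.n_mut, amat.n_mut)
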