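import numpy as np
import pandas as pd
import pytest

from grainvar.panel import GenotypePanel
from grainvar.qtlmap import (
    CriticalLd,
    LdDecayModel,
    build_qtl,
    critical_ld,
    critical_ld_from_r2,
    fit_ld_decay,
    hill_weir_r2,
    ld_blocks,
    pairwise_r2,
    prune_redundant,
)


def _panel(dosages, chroms=None, bps=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    markers = pd.DataFrame(
        {
            "marker_id": [f"m{j}" for j in range(m)],
            "chrom": chroms if chroms is not None else ["chr1"] * m,
            "bp": bps if bps is not None else np.arange(1, m + 1) * 1000,
        }
    )
    return GenotypePanel(dosages, markers, [f"g{i}" for i in range(n)])


class TestPairwiseR2:
    def test_identical_columns(self):
        rng = np.random.default_rng(0)
        c = rng.integers(0, 3, 12).astype(float)
        p = _panel(np.column_stack([c, c]))
        out = pairwise_r2(p, [(0, 1)])
        assert out["r2"].iloc[0] == pytest.approx(1.0)

    def test_coding_flip_invariance(self):
        rng = np.random.default_rng(1)
        c = rng.integers(0, 3, 12).astype(float)
        p = _panel(np.column_stack([c, 2.0 - c]))
        out = pairwise_r2(p, [(0, 1)])
        assert out["r2"].iloc[0] == pytest.approx(1.0)

    def test_hand_computed_pair(self):
        a = np.array([0, 1, 2, 2, 1, 0, 1, 2], dtype=float)
        b = np.array([0, 0, 2, 1, 1, 0, 2, 2], dtype=float)
        num = np.sum((a - a.mean()) * (b - b.mean()))
        den = np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
        expected = (num / den) ** 2
        p = _panel(np.column_stack([a, b]))
        assert pairwise_r2(p, [(0, 1)])["r2"].iloc[0] == pytest.approx(
            expected, abs=1e-12
        )

    def test_zero_variance_flagged(self):
        p = _panel(np.column_stack([np.ones(8), np.arange(8.0) % 3]))
        out = pairwise_r2(p, [(0, 1)])
        assert out["undefined"].iloc[0]


class TestCriticalLd:
    def test_fixed_vector_percentile(self):
        r2 = np.arange(0.01, 1.005, 0.01)  # 0.01 .. 1.00
        expected = np.percentile(r2, 95.0)
        assert critical_ld_from_r2(r2) == pytest.approx(expected, abs=1e-12)

    def test_independent_markers_low(self):
        rng = np.random.default_rng(2)
        d = rng.binomial(2, 0.5, (500, 200)).astype(float)
        chroms = ["chr1"] * 100 + ["chr2"] * 100
        crit = critical_ld(_panel(d, chroms=chroms), n_pairs=500, seed=0)
        assert crit.value < 0.05

    def test_bounds_and_methods(self):
        rng = np.random.default_rng(3)
        d = rng.binomial(2, 0.3, (50, 60)).astype(float)
        chroms = ["chr1"] * 30 + ["chr2"] * 30
        for method in ("empirical-95th", "parametric-sqrt"):
            c = critical_ld(_panel(d, chroms=chroms), n_pairs=200, seed=1,
                            method=method)
            assert 0.0 <= c.value <= 1.0
            assert c.method == method

    def test_needs_two_chromosomes(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError):
            critical_ld(_panel(rng.binomial(2, 0.5, (20, 10)).astype(float)),
                        n_pairs=10, seed=0)


class TestPrune:
    def test_duplicate_column(self):
        rng = np.random.default_rng(5)
        c = rng.integers(0, 3, 20).astype(float)
        other = rng.binomial(2, 0.5, 20).astype(float)
        p = _panel(np.column_stack([c, c, other]))
        out = prune_redundant(p)
        assert "m0" in set(out.markers["marker_id"])
        assert "m1" not in set(out.markers["marker_id"])

    def test_three_identical(self):
        rng = np.random.default_rng(6)
        c = rng.integers(0, 3, 20).astype(float)
        p = _panel(np.column_stack([c, c, c]))
        out = prune_redundant(p)
        assert out.n_markers == 1

    def test_matches_greedy_oracle(self):
        """6-marker chromosome: retained set equals a hand-run greedy scan."""
        rng = np.random.default_rng(7)
        base = rng.binomial(2, 0.5, 40).astype(float)
        cols = [base]
        for noise in (0.0, 2.0, 0.1, 3.0, 0.2):
            c = np.clip(np.round(base + rng.normal(0, noise, 40)), 0, 2)
            cols.append(c)
        mat = np.column_stack(cols)
        p = _panel(mat)
        out = prune_redundant(p, threshold=0.9)

        kept = []
        for j in range(mat.shape[1]):
            ok = True
            for k in kept:
                r = np.corrcoef(mat[:, j], mat[:, k])[0, 1]
                if r * r > 0.9:
                    ok = False
                    break
            if ok:
                kept.append(j)
        assert list(out.markers["marker_id"]) == [f"m{j}" for j in kept]

    def test_postcondition_no_high_ld_pair(self):
        rng = np.random.default_rng(8)
        base = rng.binomial(2, 0.4, (60, 10)).astype(float)
        # add noisy copies to create redundancy
        extra = np.clip(
            np.round(base + rng.normal(0, 0.3, base.shape)), 0, 2
        )
        mat = np.column_stack([base, extra])
        p = _panel(mat)
        out = prune_redundant(p, threshold=0.9)
        d = out.dosages
        keepable = d.std(axis=0) > 0
        r = np.corrcoef(d[:, keepable].T)
        np.fill_diagonal(r, 0.0)
        assert np.nanmax(r * r) <= 0.9 + 1e-12


def _avg_linkage_oracle(d: np.ndarray, cut: float) -> list[set]:
    """Naive agglomerative average-linkage with a height cut."""
    clusters = [{i} for i in range(d.shape[0])]
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                dist = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or dist < best[0]:
                    best = (dist, a, b)
        if best[0] > cut:
            break
        _, a, b = best
        clusters[a] = clusters[a] | clusters[b]
        del clusters[b]
    return clusters


class TestLdBlocks:
    @staticmethod
    def _sig(panel, cols):
        mk = panel.markers.iloc[cols]
        return pd.DataFrame(
            {
                "marker_id": mk["marker_id"].to_numpy(),
                "chrom": mk["chrom"].to_numpy(),
                "bp": mk["bp"].to_numpy(),
                "lod": 4.0,
            }
        )

    def test_singleton(self):
        rng = np.random.default_rng(9)
        p = _panel(rng.binomial(2, 0.5, (20, 5)).astype(float))
        blocks = ld_blocks(self._sig(p, [2]), p, 0.2)
        assert len(blocks) == 1
        assert blocks["start_bp"].iloc[0] == blocks["end_bp"].iloc[0]

    def test_perfect_ld_single_block(self):
        rng = np.random.default_rng(10)
        c = rng.integers(0, 3, 20).astype(float)
        p = _panel(np.column_stack([c, c]))
        blocks = ld_blocks(self._sig(p, [0, 1]), p, 0.999)
        assert len(blocks) == 1

    def test_matches_average_linkage_oracle(self):
        """4 significant SNPs: clusters equal an independently coded
        agglomerative average-linkage at the same cut."""
        rng = np.random.default_rng(11)
        base = rng.binomial(2, 0.5, 30).astype(float)
        c2 = np.clip(np.round(base + rng.normal(0, 0.4, 30)), 0, 2)
        far = rng.binomial(2, 0.5, 30).astype(float)
        far2 = np.clip(np.round(far + rng.normal(0, 0.4, 30)), 0, 2)
        p = _panel(np.column_stack([base, c2, far, far2]))
        crit = 0.7
        blocks = ld_blocks(self._sig(p, [0, 1, 2, 3]), p, crit)

        r = np.corrcoef(p.dosages.T)
        d = 1.0 - r * r
        np.fill_diagonal(d, 0.0)
        oracle = _avg_linkage_oracle(d, 1.0 - crit)
        got = {frozenset(b) for b in
               (tuple(sorted(int(m[1:]) for m in row["members"]))
                for _, row in blocks.iterrows())}
        want = {frozenset(c) for c in oracle}
        assert got == want

    def test_order_invariance(self):
        rng = np.random.default_rng(12)
        p = _panel(rng.binomial(2, 0.4, (40, 6)).astype(float))
        sig = self._sig(p, [0, 1, 2, 3, 4, 5])
        b1 = ld_blocks(sig, p, 0.3)
        b2 = ld_blocks(sig.iloc[::-1].reset_index(drop=True), p, 0.3)
        assert {tuple(sorted(m)) for m in b1["members"]} == {
            tuple(sorted(m)) for m in b2["members"]
        }


class TestLdDecay:
    def test_rho_recovery_on_curve(self):
        """r^2 drawn exactly on the Hill-Weir curve: rho recovered within 5%."""
        rho_true, n = 2e-6, 200
        d = np.linspace(1e3, 5e6, 400)
        r2 = hill_weir_r2(d, rho_true, n)
        from scipy.optimize import curve_fit

        popt, _ = curve_fit(lambda dd, rho: hill_weir_r2(dd, rho, n), d, r2,
                            p0=[1e-7], bounds=(1e-15, 1.0))
        assert abs(popt[0] - rho_true) / rho_true < 0.05

    def test_fit_on_panel_and_extension(self):
        from grainvar.simdata import simulate_genotypes
        from conftest import small_cfg

        cfg = small_cfg(seed=21, missing_rate=0.0)
        panel = simulate_genotypes(cfg)
        crit = critical_ld(panel, n_pairs=2000, seed=0)
        model = fit_ld_decay(panel, crit, seed=0, n_pairs=4000)
        assert model.rho > 0
        if np.isfinite(model.extension_bp) and model.extension_bp > 0:
            val = hill_weir_r2(
                np.array([model.extension_bp]), model.rho, model.n
            )[0]
            assert abs(val - crit.value) < 1e-6

    def test_monotone_decay(self):
        d = np.logspace(2, 8, 50)
        r2 = hill_weir_r2(d, 1e-6, 300)
        assert np.all(np.diff(r2) < 0)


class TestBuildQtl:
    @staticmethod
    def _blocks(rows):
        return pd.DataFrame(
            rows, columns=["block_id", "chrom", "start_bp", "end_bp", "members"]
        )

    def test_disjoint_blocks(self):
        blocks = self._blocks([
            ("b1", "chr1", 1_000_000, 2_000_000, ("m1",)),
            ("b2", "chr1", 50_000_000, 51_000_000, ("m2",)),
        ])
        out = build_qtl(blocks, 1_000_000.0)
        assert len(out) == 2

    def test_overlapping_extensions_merge(self):
        blocks = self._blocks([
            ("b1", "chr1", 1_000_000, 2_000_000, ("m1",)),
            ("b2", "chr1", 3_000_000, 4_000_000, ("m2",)),
        ])
        out = build_qtl(blocks, 600_000.0)
        assert len(out) == 1
        assert out["start_bp"].iloc[0] == 400_000
        assert out["end_bp"].iloc[0] == 4_600_000
        assert set(out["members"].iloc[0]) == {"m1", "m2"}

    def test_matches_sweep_line_oracle(self):
        """5-block toy: merged intervals equal an independent sweep."""
        rng = np.random.default_rng(13)
        rows = []
        for i in range(5):
            s = int(rng.integers(1, 80_000_000))
            e = s + int(rng.integers(0, 5_000_000))
            rows.append((f"b{i}", "chr1", s, e, (f"m{i}",)))
        ext = 2_000_000.0
        out = build_qtl(self._blocks(rows), ext)

        ivals = sorted(
            (max(s - ext, 1), e + ext) for _, _, s, e, _ in rows
        )
        merged = []
        for s, e in ivals:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        assert len(out) == len(merged)
        for (_, r), (s, e) in zip(out.iterrows(), merged):
            assert r["start_bp"] == int(s)
            assert r["end_bp"] == int(e)

    def test_qtl_count_nonincreasing_in_extension(self):
        rng = np.random.default_rng(14)
        rows = []
        for i in range(8):
            s = int(rng.integers(1, 100_000_000))
            e = s + int(rng.integers(0, 3_000_000))
            rows.append((f"b{i}", "chr1", s, e, (f"m{i}",)))
        blocks = self._blocks(rows)
        counts = [len(build_qtl(blocks, ext))
                  for ext in (0.0, 1e6, 5e6, 2e7, 1e8)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_peak_snp_max_lod(self):
        blocks = self._blocks([("b1", "chr1", 100, 200, ("mA", "mB"))])
        sig = pd.DataFrame(
            {
                "marker_id": ["mA", "mB"],
                "lod": [4.0, 7.5],
                "maf": [0.2, 0.3],
            }
        )
        out = build_qtl(blocks, 0.0, sig_snps=sig)
        assert out["peak_snp"].iloc[0] == "mB"
        assert out["peak_lod"].iloc[0] == pytest.approx(7.5)
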