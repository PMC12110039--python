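"""ssGSEA scoring and density-pathway correlation integration."""

import numpy as np
import pandas as pd
import pytest

from spatialtme.exceptions import (
    EmptySetError,
    InsufficientDataError,
    JoinError,
)
from spatialtme.pathway_scores import (
    cross_platform_check,
    integrate_density_pathways,
    score_matrix,
    ssgsea_score,
)


def _brute_force_es(expr, in_set, weight=0.25):
    """Independent direct evaluation of the running-sum definition."""
    n = len(expr)
    order = np.argsort(-np.asarray(expr), kind="stable")
    ranks = pd.Series(expr).rank().to_numpy()
    hits = [i for i in order if in_set[i]]
    denom = sum(ranks[i] ** weight for i in hits)
    n_out = n - len(hits)
    es = 0.0
    p_in = p_out = 0.0
    for i in order:
        if in_set[i]:
            p_in += ranks[i] ** weight / denom
        else:
            p_out += 1.0 / n_out
        es += p_in - p_out
    return es


class TestSsgsea:
    def test_matches_hand_enumerated_running_sum(self):
        expr = np.array([9.0, 1.0, 7.0, 3.0, 8.0, 2.0, 6.0, 4.0, 5.0, 0.5])
        genes = [f"g{i}" for i in range(10)]
        in_set = np.isin(genes, ["g0", "g4", "g7"])
        df = pd.DataFrame({"a": expr}, index=genes)
        got = ssgsea_score(df, ["g0", "g4", "g7"], rescale=False)["a"]
        assert got == pytest.approx(_brute_force_es(expr, in_set), rel=1e-12)

    def test_top_ranked_set_is_maximal(self, rng):
        genes = [f"g{i}" for i in range(12)]
        gene_set = ["g0", "g1", "g2"]
        expr = np.arange(12, 0, -1).astype(float)  # set occupies top 3 ranks
        top = ssgsea_score(pd.DataFrame({"a": expr}, index=genes),
                           gene_set, rescale=False)["a"]
        for _ in range(200):
            perm = rng.permutation(expr)
            other = ssgsea_score(pd.DataFrame({"a": perm}, index=genes),
                                 gene_set, rescale=False)["a"]
            assert other <= top + 1e-9

    def test_invariance_under_monotone_transforms(self, rng):
        genes = [f"g{i}" for i in range(20)]
        expr = rng.uniform(1, 10, 20)
        df = pd.DataFrame({"a": expr}, index=genes)
        gene_set = genes[3:8]
        base = ssgsea_score(df, gene_set, rescale=False)["a"]
        shifted = ssgsea_score(df + 100.0, gene_set, rescale=False)["a"]
        powered = ssgsea_score(df**3, gene_set, rescale=False)["a"]
        assert shifted == pytest.approx(base, rel=1e-12)
        assert powered == pytest.approx(base, rel=1e-12)

    def test_empty_overlap_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0]}, index=["g1", "g2"])
        with pytest.raises(EmptySetError):
            ssgsea_score(df, ["absent"])

    def test_score_matrix_shape(self, rng):
        genes = [f"g{i}" for i in range(30)]
        expr = pd.DataFrame(
            rng.uniform(0, 10, size=(30, 5)), index=genes,
            columns=[f"a{i}" for i in range(5)],
        )
        sets = {"S1": genes[:5], "S2": genes[10:20]}
        mat = score_matrix(expr, sets)
        assert mat.shape == (2, 5)
        assert np.isfinite(mat.to_numpy()).all()


class TestSpearmanClosedForm:
    def test_tie_free_rho_matches_formula(self, rng):
        from spatialtme._stats import spearman

        x = rng.permutation(np.arange(1.0, 13.0))
        y = rng.permutation(np.arange(1.0, 13.0))
        rho, _ = spearman(x, y)
        d = pd.Series(x).rank() - pd.Series(y).rank()
        n = len(x)
        assert rho == pytest.approx(
            1 - 6 * float((d**2).sum()) / (n * (n**2 - 1)), rel=1e-12
        )


def _setup_integration(n_patients=6, seed=0, coupled=False):
    rng = np.random.default_rng(seed)
    patients = [f"P{i}" for i in range(n_patients)]
    annot = pd.DataFrame(
        {
            "aoi_id": [f"{p}_R1_PanCK" for p in patients],
            "patient_id": patients,
            "roi_id": [f"{p}_R1" for p in patients],
            "compartment": "PanCK",
            "group": "recur",
        }
    )
    dens_vals = rng.uniform(10, 500, n_patients)
    densities = pd.DataFrame(
        {
            "sample": patients,
            "compartment": "tumor_nest",
            "phenotype": "macrophage",
            "density": dens_vals,
            "area_mm2": 1.0,
        }
    )
    score_vals = 0.01 * dens_vals if coupled else rng.uniform(size=n_patients)
    scores = pd.DataFrame(
        [score_vals], index=["PATHWAY_X"], columns=annot["aoi_id"]
    )
    return densities, scores, annot


class TestIntegration:
    def test_monotone_coupling_gives_rho_one(self):
        densities, scores, annot = _setup_integration(coupled=True)
        res = integrate_density_pathways(
            densities, scores, annot, "recur", phenotypes=("macrophage",)
        )
        assert res.rho.loc["macrophage", "PATHWAY_X"] == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        densities, scores, annot = _setup_integration(coupled=True)
        scores = -scores
        res = integrate_density_pathways(
            densities, scores, annot, "recur", phenotypes=("macrophage",)
        )
        assert res.rho.loc["macrophage", "PATHWAY_X"] == pytest.approx(-1.0)

    def test_insufficient_pairs_rejected(self):
        densities, scores, annot = _setup_integration(n_patients=3)
        with pytest.raises(InsufficientDataError):
            integrate_density_pathways(
                densities, scores, annot, "recur", phenotypes=("macrophage",)
            )

    def test_null_pairs_are_calibrated(self):
        """Independent density/score pairs at n=10: mean rho near 0 and
        ~5% rejections at alpha = 0.05 over 1,000 simulations."""
        rng = np.random.default_rng(42)
        from spatialtme._stats import spearman

        rhos, rejects = [], 0
        for _ in range(1000):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            rho, p = spearman(x, y)
            rhos.append(rho)
            rejects += p < 0.05
        assert abs(np.mean(rhos)) < 0.05
        assert 0.03 <= rejects / 1000 <= 0.07


class TestCrossPlatform:
    def test_constant_marker_is_flagged(self):
        densities, scores, annot = _setup_integration()
        expr = pd.DataFrame(
            np.full((1, len(annot)), 7.0), index=["CD68"], columns=annot["aoi_id"]
        )
        res = cross_platform_check(densities, expr, "CD68", annot,
                                   phenotype="macrophage")
        assert res.flagged and np.isnan(res.rho)

    def test_unmatched_samples_rejected(self):
        densities, scores, annot = _setup_integration()
        densities = densities.assign(sample=[f"X{i}" for i in range(len(densities))])
        expr = pd.DataFrame(
            np.ones((1, len(annot))), index=["CD68"], columns=annot["aoi_id"]
        )
        with pytest.raises(JoinError):
            cross_platform_check(densities, expr, "CD68", annot)

    def test_coupled_generator_recovers_positive_correlation(self):
        """Per-patient macrophage multipliers drive both the CD68 signal in
        expression and the mIF macrophage density, so the cross-platform
        Spearman gate must be strongly positive in most cohorts."""
        from spatialtme import synthetic
        from spatialtme.geomx_qc import q3_normalize
        from spatialtme.mif_spatial import density_table

        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cohort = synthetic.generate_cohort(12, 8, seed)
            effects = synthetic.generate_patient_effects(cohort, seed + 500)
            design = synthetic.default_design()
            counts, flags, annot = synthetic.generate_aoi_counts(
                cohort, design, seed=seed + 1000, patient_effects=effects
            )
            maps = synthetic.cohort_cell_maps(
                cohort, seed=seed + 2000, density_scale=effects
            )
            norm = q3_normalize(counts.loc[~flags])
            densities = density_table(maps, phenotypes=("macrophage",))
            res = cross_platform_check(densities, norm.values, "CD68", annot)
            hits += res.rho > 0.5
        assert hits >= 0.9 * n_seeds
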