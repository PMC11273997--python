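import numpy as np
import pytest

from latentlink import fa_baseline, metrics, simulate
from latentlink.alignment import procrustes_align


@pytest.fixture(scope="module")
def linear_solution(linear_dataset):
    sol = fa_baseline.fit_fa(
        linear_dataset.responses, 1, reference_loadings=linear_dataset.spec.loadings
    )
    return fa_baseline.estimate_scores(sol, linear_dataset.responses)


class TestFit:
    def test_loadings_recover_generating_value(self, linear_solution):
        lam = linear_solution.loadings.ravel()
        assert np.all(np.abs(lam - 0.8) < 0.06)
        assert linear_solution.converged

    def test_both_metric_conventions_reported(self, linear_solution):
        # covariance metric: sum lambda^2 ~ 0.64; correlation metric ~ 0.64/0.84
        assert np.allclose(linear_solution.communalities, 0.64, atol=0.08)
        cc = linear_solution.communalities_correlation
        assert np.all((cc > 0.6) & (cc < 0.9))
        assert np.allclose(
            linear_solution.standardized_loadings.ravel(),
            0.8 / np.sqrt(0.84),
            atol=0.05,
        )

    def test_matches_r_factanal_convention(self, linear_dataset):
        """sklearn's EM-ML agrees with an independent ML implementation."""
        rfact = pytest.importorskip("subprocess")
        import subprocess, tempfile, os

        x = linear_dataset.responses
        with tempfile.TemporaryDirectory() as td:
            path = os.path.join(td, "x.csv")
            np.savetxt(path, x, delimiter=",")
            out = subprocess.run(
                [
                    "Rscript", "-e",
                    f'x<-as.matrix(read.csv("{path}",header=FALSE));'
                    'f<-factanal(x,1,rotation="none");'
                    'cat(as.numeric(f$loadings)*apply(x,2,sd))',
                ],
                capture_output=True, text=True, timeout=120,
            )
            if out.returncode != 0:
                pytest.skip("Rscript unavailable")
            r_loadings = np.abs(np.array(out.stdout.split(), dtype=float))
        sol = fa_baseline.fit_fa(x, 1, reference_loadings=linear_dataset.spec.loadings)
        assert np.allclose(np.abs(sol.loadings.ravel()), r_loadings, atol=0.02)

    def test_noise_free_exact_low_rank(self):
        spec = simulate.make_spec(residual_variance=0.0)
        ds = simulate.simulate_dataset(spec, 400, seed=2)
        sol = fa_baseline.fit_fa(ds.responses, 1, reference_loadings=spec.loadings)
        sol = fa_baseline.estimate_scores(sol, ds.responses)
        rec = fa_baseline.reconstruct(sol)
        # reconstruction is exact and equals the rank-1 least-squares fit
        assert np.allclose(rec, ds.responses, atol=1e-8)
        xc = ds.responses - ds.responses.mean(axis=0)
        u, s, vt = np.linalg.svd(xc, full_matrices=False)
        rank1 = u[:, :1] * s[:1] @ vt[:1] + ds.responses.mean(axis=0)
        assert np.allclose(rec, rank1, atol=1e-8)

    def test_two_factor_simple_structure_after_alignment(self):
        spec = simulate.make_spec(n_factors=2)
        ds = simulate.simulate_dataset(spec, 1000, seed=3)
        sol = fa_baseline.fit_fa(ds.responses, 2, reference_loadings=spec.loadings)
        on_block = sol.loadings[spec.loadings != 0]
        off_block = sol.loadings[spec.loadings == 0]
        assert np.all(np.abs(on_block - 0.8) < 0.08)
        assert np.all(np.abs(off_block) < 0.08)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="subjects"):
            fa_baseline.fit_fa(np.zeros((5, 8)), 1)


class TestScores:
    def test_bartlett_scores_conditionally_unbiased(self, linear_dataset, linear_solution):
        xi = linear_dataset.true_scores.ravel()
        est = linear_solution.est_scores.ravel()
        slope = np.polyfit(xi, est, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.05)
        assert est.mean() == pytest.approx(0.0, abs=1e-8)

    def test_score_error_matches_sampling_theory(self, linear_dataset, linear_solution):
        # Bartlett error sd under the recipe: sqrt(0.2 / (8 * 0.64)) ~ 0.198
        rep = metrics.score_recovery(
            linear_dataset.true_scores, linear_solution.est_scores
        )
        assert rep.rmse == pytest.approx(np.sqrt(0.2 / 5.12), abs=0.03)

    def test_regression_scores_are_shrunk(self, linear_dataset, linear_solution):
        reg = fa_baseline.estimate_scores(
            linear_solution, linear_dataset.responses, method="regression"
        )
        assert reg.est_scores.var() < linear_solution.est_scores.var()

    def test_deterministic_given_same_input(self, linear_dataset, linear_solution):
        again = fa_baseline.fit_fa(
            linear_dataset.responses, 1,
            reference_loadings=linear_dataset.spec.loadings,
        )
        again = fa_baseline.estimate_scores(again, linear_dataset.responses)
        assert np.array_equal(again.est_scores, linear_solution.est_scores)

    def test_noise_free_scores_recover_truth(self):
        spec = simulate.make_spec(residual_variance=0.0)
        ds = simulate.simulate_dataset(spec, 400, seed=2)
        sol = fa_baseline.fit_fa(ds.responses, 1, reference_loadings=spec.loadings)
        sol = fa_baseline.estimate_scores(sol, ds.responses)
        # scores recover the truth up to the sample sd of the drawn scores
        c = ds.true_scores.ravel().std(ddof=1)
        assert np.allclose(sol.est_scores.ravel() * c, ds.true_scores.ravel()
                           - ds.true_scores.mean(), atol=1e-6)


class TestReconstruct:
    def test_reconstruction_identity(self, linear_solution):
        rec = fa_baseline.reconstruct(linear_solution)
        manual = (
            linear_solution.intercepts
            + linear_solution.est_scores @ linear_solution.loadings.T
        )
        assert np.array_equal(rec, manual)

    def test_zero_loadings_give_intercepts(self, linear_solution):
        import dataclasses

        sol = dataclasses.replace(
            linear_solution, loadings=np.zeros_like(linear_solution.loadings)
        )
        rec = fa_baseline.reconstruct(sol)
        assert np.allclose(rec, sol.intercepts)

    def test_requires_scores(self, linear_dataset):
        sol = fa_baseline.fit_fa(linear_dataset.responses, 1)
        with pytest.raises(ValueError, match="estimate scores"):
            fa_baseline.reconstruct(sol)


def test_procrustes_subsumes_sign_flip(rng):
    ref = rng.normal(size=(50, 1))
    aligned, r = procrustes_align(-ref, ref)
    assert np.allclose(aligned, ref)
    assert r[0, 0] == pytest.approx(-1.0)
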