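"""Count-model fitters: identities, simulation recovery, and R cross-checks."""

import subprocess

import numpy as np
import pytest

from folliprof.models import (
    FitError,
    contrast_test,
    fit_lognormal_poisson_glmm,
    fit_od_poisson_glm,
    fit_od_poisson_glmm,
    make_design,
    pairwise_contrasts,
    tukey_adjust,
)
from conftest import make_metadata


@pytest.fixture
def two_group_meta():
    """2 groups × 10 subjects × 3 replicates."""
    return make_metadata(
        [(f"{g}{s}", g, "scalp", "total", 3) for g in ("AA", "CA") for s in range(10)]
    )


@pytest.fixture
def site_meta():
    """4 sites within each of 10 subjects, 3 replicates each."""
    return make_metadata(
        [
            (f"S{s}", "CA", site, "total", 3)
            for s in range(10)
            for site in ("axillary", "facial", "pubic", "scalp")
        ]
    )


class TestOdPoissonGLM:
    def test_dispersion_near_one_under_pure_poisson(self, two_group_meta, rng):
        d = make_design(two_group_meta, two_group_meta.sample_ids, fixed=["group"])
        reps = 5  # 5 × 60 = 300 observations worth of chi-square
        phis = []
        for _ in range(reps):
            y = rng.poisson(40.0, size=d.n_obs)
            phis.append(fit_od_poisson_glm(y, d).phi)
        assert 0.85 <= np.mean(phis) <= 1.15

    def test_offset_shifts_only_the_intercept(self, two_group_meta, rng):
        sids = two_group_meta.sample_ids
        y = rng.poisson(30.0, size=len(sids)).astype(float)
        d0 = make_design(two_group_meta, sids, fixed=["group"])
        c = 0.7
        d1 = make_design(two_group_meta, sids, fixed=["group"], offset=np.full(len(sids), c))
        f0 = fit_od_poisson_glm(y, d0)
        f1 = fit_od_poisson_glm(y, d1)
        assert f1.beta[0] == pytest.approx(f0.beta[0] - c, abs=1e-8)
        assert f1.beta[1:] == pytest.approx(f0.beta[1:], abs=1e-8)

    def test_quasi_poisson_recovery(self, two_group_meta, rng):
        """phi = 3 gamma-mixed Poisson, beta = log 2: estimates recover truth."""
        d = make_design(two_group_meta, two_group_meta.sample_ids, fixed=["group"])
        x = d.matrix[:, 1]
        mu = 30.0 * np.exp(np.log(2.0) * x)
        v = 2.0 / mu  # per-observation mixing variance: Var(y) = mu + mu^2 v = 3 mu
        betas, phis = [], []
        for _ in range(150):
            y = rng.poisson(mu * rng.gamma(1.0 / v, v, size=d.n_obs))
            fit = fit_od_poisson_glm(y, d)
            betas.append(fit.beta[1])
            phis.append(fit.phi)
        mc_se = np.std(betas, ddof=1) / np.sqrt(len(betas))
        assert abs(np.mean(betas) - np.log(2.0)) < 3 * mc_se
        assert abs(np.mean(phis) - 3.0) < 0.3

    def test_too_few_observations_is_an_error(self, rng):
        meta = make_metadata([("A", "CA", "scalp", "total", 1), ("B", "CA", "scalp", "total", 1)])
        d = make_design(meta, meta.sample_ids, fixed=["subject"])
        with pytest.raises(FitError):
            fit_od_poisson_glm(np.array([3.0, 5.0]), d)

    def test_all_zero_cell_flags_boundary_without_crashing(self, two_group_meta):
        d = make_design(two_group_meta, two_group_meta.sample_ids, fixed=["group"])
        y = np.where(d.matrix[:, 1] > 0, 0.0, 20.0)
        with pytest.warns(UserWarning, match="boundary"):
            fit = fit_od_poisson_glm(y, d)
        assert fit.boundary


class TestOdPoissonGLMM:
    def test_single_subject_per_group_is_inestimable(self):
        meta = make_metadata([(f"S{g}", g, "scalp", "total", 3) for g in ("AA", "CA", "KE")])
        d = make_design(meta, meta.sample_ids, fixed=["group"], random_subject=True)
        with pytest.raises(FitError, match="confounded"):
            fit_od_poisson_glmm(np.ones(9), d)

    def test_sigma_zero_truth_lands_at_boundary(self, two_group_meta, rng):
        d = make_design(
            two_group_meta, two_group_meta.sample_ids, fixed=["group"], random_subject=True
        )
        near = 0
        reps = 60
        for _ in range(reps):
            y = rng.poisson(35.0, size=d.n_obs)
            fit = fit_od_poisson_glmm(y, d)
            near += fit.sigma_subject < 0.1
        assert near / reps >= 0.8

    def test_parameter_recovery_site_model(self, site_meta, rng):
        """sigma_subject = 0.5, beta_site = log 1.5 recovered in simulation."""
        d = make_design(site_meta, site_meta.sample_ids, fixed=["site"], random_subject=True)
        x = d.matrix[:, 3]  # scalp vs axillary (reference)
        betas, sigmas = [], []
        for _ in range(60):
            u = rng.normal(0.0, 0.5, size=d.n_groups)
            mu = 30.0 * np.exp(np.log(1.5) * x + u[d.groups])
            fit = fit_od_poisson_glmm(rng.poisson(mu), d)
            betas.append(fit.beta[3])
            sigmas.append(fit.sigma_subject)
        mc_se = np.std(betas, ddof=1) / np.sqrt(len(betas))
        assert abs(np.mean(betas) - np.log(1.5)) < 3 * mc_se
        assert abs(np.mean(sigmas) - 0.5) < 0.075  # within 15%

    def test_matches_lme4_glmer(self, two_group_meta, rng, tmp_path):
        """One dataset against lme4's Poisson GLMM.

        nAGQ=0 matches this package's estimation strategy (fixed effects
        solved at the penalized joint mode, outer search over the variance
        parameter only), so agreement is expected to tight tolerance.
        """
        d = make_design(
            two_group_meta, two_group_meta.sample_ids, fixed=["group"], random_subject=True
        )
        u = rng.normal(0.0, 0.4, size=d.n_groups)
        y = rng.poisson(25.0 * np.exp(0.5 * d.matrix[:, 1] + u[d.groups]))
        fit = fit_od_poisson_glmm(y, d)

        data = tmp_path / "d.tsv"
        with open(data, "w") as fh:
            fh.write("y\tx\tsubj\n")
            for yi, xi, gi in zip(y, d.matrix[:, 1], d.groups):
                fh.write(f"{int(yi)}\t{int(xi)}\t{gi}\n")
        script = tmp_path / "glmer.R"
        script.write_text(
            "suppressMessages(library(lme4))\n"
            f"d <- read.delim('{data}')\n"
            "m <- glmer(y ~ x + (1|subj), data=d, family=poisson, nAGQ=0)\n"
            "cat(fixef(m), sqrt(unlist(VarCorr(m))), sep='\\n')\n"
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True, check=True
        )
        b0, b1, sig = (float(v) for v in out.stdout.split())
        assert fit.beta[0] == pytest.approx(b0, abs=2e-3)
        assert fit.beta[1] == pytest.approx(b1, abs=2e-3)
        assert fit.sigma_subject == pytest.approx(sig, abs=5e-3)


@pytest.fixture
def fraction_meta():
    """10 subjects × 2 fractions × 3 replicates."""
    return make_metadata(
        [(f"S{s}", "CA", "scalp", f, 3) for s in range(10) for f in ("total", "cuticle")]
    )


class TestLognormalPoissonGLMM:
    def test_nested_consistency_with_poisson_glmm(self, fraction_meta, rng):
        """sigma_obs fixed at 0 reproduces the Poisson GLMM estimates."""
        d = make_design(
            fraction_meta, fraction_meta.sample_ids, fixed=["fraction"], random_subject=True
        )
        u = rng.normal(0.0, 0.3, size=d.n_groups)
        y = rng.poisson(30.0 * np.exp(0.4 * d.matrix[:, 1] + u[d.groups])).astype(float)
        lnp = fit_lognormal_poisson_glmm(y, d, fix_sigma_obs=0.0)
        glmm = fit_od_poisson_glmm(y, d)
        assert lnp.beta == pytest.approx(glmm.beta, abs=1e-4)
        assert lnp.sigma_subject == pytest.approx(glmm.sigma_subject, abs=1e-4)
        assert lnp.sigma_obs == 0.0

    def test_recovers_both_variance_components(self, fraction_meta, rng):
        d = make_design(
            fraction_meta, fraction_meta.sample_ids, fixed=["fraction"], random_subject=True
        )
        x = d.matrix[:, 1]
        betas, s_us, s_os = [], [], []
        for _ in range(40):
            u = rng.normal(0.0, 0.3, size=d.n_groups)
            e = rng.normal(0.0, 0.4, size=d.n_obs)
            y = rng.poisson(30.0 * np.exp(np.log(2.0) * x + u[d.groups] + e))
            fit = fit_lognormal_poisson_glmm(y, d)
            betas.append(fit.beta[1])
            s_us.append(fit.sigma_subject)
            s_os.append(fit.sigma_obs)
        mc_se = np.std(betas, ddof=1) / np.sqrt(len(betas))
        assert abs(np.mean(betas) - np.log(2.0)) < 3 * mc_se
        assert abs(np.mean(s_os) - 0.4) < 0.08  # 20%
        assert abs(np.mean(s_us) - 0.3) < 0.06  # 20%

    def test_all_zero_level_does_not_crash(self, fraction_meta):
        d = make_design(
            fraction_meta, fraction_meta.sample_ids, fixed=["fraction"], random_subject=True
        )
        y = np.where(d.matrix[:, 1] > 0, 8.0, 0.0)  # one fraction identically zero
        with pytest.warns(UserWarning, match="boundary"):
            fit = fit_lognormal_poisson_glmm(y, d)
        assert np.isfinite(fit.beta).all()

    def test_matches_glmmtmb(self, fraction_meta, rng, tmp_path):
        """One dataset against glmmTMB's subject + observation-level model."""
        d = make_design(
            fraction_meta, fraction_meta.sample_ids, fixed=["fraction"], random_subject=True
        )
        u = rng.normal(0.0, 0.3, size=d.n_groups)
        e = rng.normal(0.0, 0.4, size=d.n_obs)
        y = rng.poisson(30.0 * np.exp(0.6 * d.matrix[:, 1] + u[d.groups] + e))
        fit = fit_lognormal_poisson_glmm(y, d)

        data = tmp_path / "d.tsv"
        with open(data, "w") as fh:
            fh.write("y\tx\tsubj\tobs\n")
            for i, (yi, xi, gi) in enumerate(zip(y, d.matrix[:, 1], d.groups)):
                fh.write(f"{int(yi)}\t{int(xi)}\t{gi}\t{i}\n")
        script = tmp_path / "tmb.R"
        script.write_text(
            "suppressMessages(library(glmmTMB))\n"
            f"d <- read.delim('{data}')\n"
            "d$subj <- factor(d$subj); d$obs <- factor(d$obs)\n"
            "m <- glmmTMB(y ~ x + (1|subj) + (1|obs), data=d, family=poisson)\n"
            "v <- VarCorr(m)$cond\n"
            "cat(fixef(m)$cond, sqrt(v$subj[1,1]), sqrt(v$obs[1,1]), sep='\\n')\n"
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True, check=True
        )
        b0, b1, sig_u, sig_o = (float(v) for v in out.stdout.split())
        assert fit.beta[0] == pytest.approx(b0, abs=0.02)
        assert fit.beta[1] == pytest.approx(b1, abs=0.02)
        assert fit.sigma_subject == pytest.approx(sig_u, abs=0.02)
        assert fit.sigma_obs == pytest.approx(sig_o, abs=0.02)


class TestContrasts:
    def make_fit(self, two_group_meta, rng):
        d = make_design(two_group_meta, two_group_meta.sample_ids, fixed=["group"])
        y = rng.poisson(30.0, size=d.n_obs)
        return fit_od_poisson_glm(y, d), d

    def test_zero_contrast_is_an_error(self, two_group_meta, rng):
        fit, d = self.make_fit(two_group_meta, rng)
        with pytest.raises(ValueError, match="zero-variance"):
            contrast_test(fit, np.zeros(d.n_params))

    def test_ci_brackets_the_estimate(self, two_group_meta, rng):
        fit, d = self.make_fit(two_group_meta, rng)
        c = contrast_test(fit, d.contrast_vector("group", "CA", "AA"))
        assert c.ci_low <= c.estimate <= c.ci_high

    def test_tukey_reduces_to_unadjusted_p_for_two_levels(self, two_group_meta, rng):
        fit, _ = self.make_fit(two_group_meta, rng)
        (adj,) = tukey_adjust(pairwise_contrasts(fit, "group"), k=2)
        assert adj.p_adjusted == pytest.approx(adj.p_raw, abs=1e-6)

    def test_tukey_never_decreases_p(self, site_meta, rng):
        d = make_design(site_meta, site_meta.sample_ids, fixed=["site"], random_subject=True)
        u = rng.normal(0.0, 0.3, size=d.n_groups)
        y = rng.poisson(30.0 * np.exp(u[d.groups]))
        fit = fit_od_poisson_glmm(y, d)
        for c in tukey_adjust(pairwise_contrasts(fit, "site"), k=4):
            assert c.p_adjusted >= c.p_raw

    def test_incomplete_pairwise_family_is_an_error(self, site_meta, rng):
        d = make_design(site_meta, site_meta.sample_ids, fixed=["site"], random_subject=True)
        y = rng.poisson(30.0, size=d.n_obs)
        fit = fit_od_poisson_glmm(y, d)
        with pytest.raises(ValueError, match="pairwise"):
            tukey_adjust(pairwise_contrasts(fit, "site")[:-1], k=4)
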