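"""Global chi-square fitting of PDA histograms.

All bin durations of all datasets are fitted simultaneously with a
derivative-free simplex search on the summed Pearson chi-square.  The
state distances, the static-state distance and the width fraction are
global over datasets; the interconversion rates (dynamic model) or state
areas (static model) are per dataset — for a two-dataset comparison with
the dynamic three-state model the free parameters are exactly
``R1, R2, R_static, F, 2 x k12, 2 x k21, 2 x A3`` (10 in total).

Confidence intervals for the rate constants come from a profile
chi-square scan (each rate fixed on a grid, all other parameters
re-optimized; the 95% bound is the ``delta chi2 = 3.84`` crossing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

from .dataset import PdaDataset
from .model import (PdaModel, _kernel_for, _eps_weights_dynamic,
                    _eps_weights_static, default_epr_edges)

__all__ = ["PdaFitResult", "global_fit", "confidence_intervals",
           "dwell_and_pdf", "runs_test_pvalue"]

_MIN_EXPECTED = 4.0          # bins below this expected count are excluded
DWELL_CENSOR_MS = 5.0        # dwell times above this are reported censored


# ----------------------------------------------------------------------
# parameter packing
# ----------------------------------------------------------------------

def _logit(p):
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return np.log(p / (1 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _pack(model: PdaModel):
    theta = [np.log(model.R1), np.log(model.R2)]
    names = ["R1", "R2"]
    if model.R_static > 0:
        theta.append(np.log(model.R_static))
        names.append("R_static")
    theta.append(_logit(model.width_fraction))
    names.append("width_fraction")
    if model.kind == "dynamic":
        for d in range(model.n_datasets):
            theta += [np.log(max(model.k12[d], 1e-6)),
                      np.log(max(model.k21[d], 1e-6))]
            names += [f"k12[{d}]", f"k21[{d}]"]
            if model.R_static > 0:
                theta.append(_logit(model.A3[d]))
                names.append(f"A3[{d}]")
    else:
        for d in range(model.n_datasets):
            a1, a2, a3 = model.areas[d]
            theta += [_logit(a1), _logit(a2 / max(1 - a1, 1e-9))]
            names += [f"A1[{d}]", f"A2|rest[{d}]"]
    return np.array(theta), names


def _unpack(theta, template: PdaModel):
    i = 0
    kw = {}
    kw["R1"] = float(np.exp(theta[i])); i += 1
    kw["R2"] = float(np.exp(theta[i])); i += 1
    if template.R_static > 0:
        kw["R_static"] = float(np.exp(theta[i])); i += 1
    kw["width_fraction"] = float(np.clip(_expit(theta[i]), 1e-4, 0.5)); i += 1
    if template.kind == "dynamic":
        k12, k21, a3 = [], [], []
        for d in range(template.n_datasets):
            # clamp to a physically meaningful range; the simplex can
            # otherwise wander into numerically degenerate rates
            k12.append(float(np.clip(np.exp(theta[i]), 1e-6, 1e5))); i += 1
            k21.append(float(np.clip(np.exp(theta[i]), 1e-6, 1e5))); i += 1
            if template.R_static > 0:
                a3.append(float(_expit(theta[i]))); i += 1
            else:
                a3.append(0.0)
        kw.update(k12=k12, k21=k21, A3=a3)
    else:
        areas = []
        for d in range(template.n_datasets):
            a1 = float(_expit(theta[i])); i += 1
            a2 = float(_expit(theta[i])) * (1 - a1); i += 1
            areas.append((a1, a2, max(1 - a1 - a2, 0.0)))
        kw["areas"] = areas
    return template.copy(**kw)


# ----------------------------------------------------------------------
# objective
# ----------------------------------------------------------------------

class _Objective:
    """Cached kernels + observed histograms; evaluates global chi2."""

    def __init__(self, datasets, template, edges=None, fixed=None,
                 kernels=None):
        self.datasets = list(datasets)
        self.template = template
        self.edges = default_epr_edges() if edges is None else edges
        self.fixed = dict(fixed or {})
        self.kernels = kernels if kernels is not None else {}
        self.observed = {}
        for d, ds in enumerate(self.datasets):
            for T in ds.bin_durations:
                if (d, T) not in self.kernels:
                    self.kernels[(d, T)] = _kernel_for(ds, T, self.edges)
                self.observed[(d, T)] = ds.histogram(T, self.edges)
        self.n_eval = 0

    def histograms(self, model):
        out = {}
        for d, ds in enumerate(self.datasets):
            for T in ds.bin_durations:
                kern = self.kernels[(d, T)]
                if model.kind == "dynamic":
                    w = _eps_weights_dynamic(model, ds, d, T, kern.eps_grid)
                else:
                    w = _eps_weights_static(model, ds, d, kern.eps_grid)
                out[(d, T)] = kern.expected(w)
        return out

    def chi2_parts(self, model):
        """Per-histogram (chi2, n_used) and weighted residuals."""
        parts, residuals = {}, {}
        for key, exp in self.histograms(model).items():
            obs = self.observed[key]
            use = exp >= _MIN_EXPECTED
            r = np.zeros_like(exp)
            r[use] = (obs[use] - exp[use]) / np.sqrt(exp[use])
            parts[key] = (float(np.sum(r[use] ** 2)), int(use.sum()))
            residuals[key] = r
        return parts, residuals

    def chi2(self, theta):
        self.n_eval += 1
        model = self.make_model(theta)
        parts, _ = self.chi2_parts(model)
        return sum(c for c, _ in parts.values())

    def make_model(self, theta):
        model = _unpack(theta, self.template)
        for key, v in self.fixed.items():
            if isinstance(key, tuple):
                name, d = key
                lst = list(getattr(model, name))
                lst[d] = v
                model = model.copy(**{name: lst})
            else:
                model = model.copy(**{key: v})
        return model


# ----------------------------------------------------------------------
# results
# ----------------------------------------------------------------------

@dataclass
class PdaFitResult:
    """Outcome of a global PDA fit."""

    model: PdaModel
    chi2: float
    n_points: int
    n_free: int
    chi2_red: float
    chi2_red_per_histogram: dict
    residuals: dict
    converged: bool
    runs_pvalues: dict = field(default_factory=dict)
    objective: object = None

    @property
    def acceptable(self):
        """Documented goodness criteria: chi2_red < 3, trend-free residuals."""
        trends = [p < 0.01 for p in self.runs_pvalues.values()]
        return self.chi2_red < 3.0 and not any(trends)


def runs_test_pvalue(residuals):
    """Wald-Wolfowitz runs test on the signs of weighted residuals.

    A low p-value indicates systematic trends (too few sign changes).
    """
    r = residuals[residuals != 0]
    if r.size < 8:
        return 1.0
    signs = r > 0
    n1 = int(signs.sum())
    n2 = signs.size - n1
    if n1 == 0 or n2 == 0:
        return 0.0
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    mu = 1 + 2 * n1 * n2 / (n1 + n2)
    var = (2 * n1 * n2 * (2 * n1 * n2 - n1 - n2)
           / ((n1 + n2) ** 2 * (n1 + n2 - 1)))
    if var <= 0:
        return 1.0
    z = (runs - mu) / np.sqrt(var)
    return float(2 * norm.sf(abs(z)))


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------

def global_fit(datasets, model0: PdaModel, n_restarts=5, seed=0,
               max_iter=4000, edges=None, fixed=None,
               restart_scale=0.3, kernels=None) -> PdaFitResult:
    """Simplex minimization of the summed chi-square over all histograms.

    Parameters
    ----------
    datasets : sequence of PdaDataset
        One per sample; every dataset contributes all its bin durations.
    model0 : PdaModel
        Initial model; also defines the linking structure (its per-dataset
        lists must match ``len(datasets)``).
    n_restarts : int
        Seeded random restarts around the best point so far (guards
        against local minima of the simplex search).
    fixed : dict, optional
        Model fields clamped to given values (used by profile scans).

    Returns
    -------
    PdaFitResult
        Best model with per-histogram reduced chi-square, weighted
        residuals and runs-test p-values; ``converged`` is False if the
        simplex exhausted ``max_iter`` in every start.
    """
    if not datasets:
        raise ValueError("at least one dataset is required")
    if model0.n_datasets != len(datasets):
        raise ValueError("model0 per-dataset parameters do not match the "
                         "number of datasets")
    obj = _Objective(datasets, model0, edges, fixed, kernels)
    rng = np.random.default_rng(seed)
    theta0, names = _pack(model0)
    rate_dims = np.array([n.startswith(("k12", "k21")) for n in names])
    best = None
    converged = False
    start = theta0
    if rate_dims.any() and n_restarts > 1:
        # the chi-square surface has a spurious fast-exchange basin; probe
        # rate decades with short simplex runs and start from the best
        probes = [theta0]
        for k_probe in (0.1, 0.3, 1.0, 3.0, 10.0):
            th = theta0.copy()
            th[rate_dims] = np.log(k_probe)
            probes.append(th)
        scored = []
        for th in probes:
            r = minimize(obj.chi2, th, method="Nelder-Mead",
                         options={"maxiter": 400, "xatol": 1e-3,
                                  "fatol": 1e-2, "adaptive": True})
            scored.append(r)
        start = min(scored, key=lambda r: r.fun).x
    for attempt in range(max(1, n_restarts)):
        res = minimize(obj.chi2, start, method="Nelder-Mead",
                       options={"maxiter": max_iter, "xatol": 1e-4,
                                "fatol": 1e-3, "adaptive": True})
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or res.success
        if attempt % 2 == 0 and rate_dims.any():
            # the fast-exchange manifold is a classic local trap: probe
            # other rate decades from the user's initial guess
            start = theta0 + restart_scale * rng.standard_normal(theta0.size)
            start[rate_dims] = (theta0[rate_dims]
                                + np.log(10.0) * rng.uniform(-1.5, 1.5,
                                                             rate_dims.sum()))
        else:
            start = best.x + restart_scale * rng.standard_normal(best.x.size)
    model = obj.make_model(best.x)
    parts, residuals = obj.chi2_parts(model)
    chi2 = sum(c for c, _ in parts.values())
    n_points = sum(n for _, n in parts.values())
    n_free = best.x.size
    dof = max(n_points - n_free, 1)
    per_hist = {}
    runs_p = {}
    for key, (c, n) in parts.items():
        per_hist[key] = c / max(n - n_free / len(parts), 1)
        runs_p[key] = runs_test_pvalue(residuals[key])
    return PdaFitResult(model=model, chi2=chi2, n_points=n_points,
                        n_free=n_free, chi2_red=chi2 / dof,
                        chi2_red_per_histogram=per_hist,
                        residuals=residuals, converged=converged,
                        runs_pvalues=runs_p, objective=obj)


def _refit_fixed(fit: PdaFitResult, datasets, fixed, seed=0):
    # the clamped rate stays a (flat) packed coordinate; the simplex
    # simply ignores it, and the cached kernels are reused
    return global_fit(datasets, fit.model, n_restarts=1, seed=seed,
                      max_iter=1500, fixed=fixed,
                      kernels=fit.objective.kernels)


def confidence_intervals(fit: PdaFitResult, datasets, level=0.95,
                         max_steps=12, factor=1.35, seed=0):
    """Profile-likelihood confidence intervals of the rate constants.

    Each rate is scanned on a multiplicative grid away from its estimate;
    at every grid point all remaining parameters are re-optimized and the
    bound is the interpolated ``delta chi2 = 3.84`` crossing (for 95%).
    Returns ``{(param, dataset): (lo, hi, relative_halfwidth_pct)}``.

    Raises if the fit did not converge.
    """
    if not fit.converged:
        raise ValueError("confidence intervals require a converged fit")
    if fit.model.kind != "dynamic":
        raise ValueError("rate CIs apply to the dynamic model")
    from scipy.stats import chi2 as chi2_dist

    dchi_target = chi2_dist.ppf(level, df=1)
    out = {}
    for pname in ("k12", "k21"):
        for d in range(fit.model.n_datasets):
            khat = getattr(fit.model, pname)[d]
            bounds = []
            for direction in (-1, 1):
                k = khat
                prev_k, prev_d = khat, 0.0
                bound = khat * factor ** (direction * max_steps)
                for _ in range(max_steps):
                    k = k * factor ** direction
                    sub = _refit_fixed(fit, datasets, {(pname, d): k},
                                       seed=seed)
                    dchi = sub.chi2 - fit.chi2
                    if dchi >= dchi_target:
                        # log-linear interpolation to the crossing
                        f = ((dchi_target - prev_d) / max(dchi - prev_d, 1e-12))
                        bound = prev_k * (k / prev_k) ** f
                        break
                    prev_k, prev_d = k, max(dchi, 0.0)
                bounds.append(bound)
            lo, hi = sorted(bounds)
            rel = 100.0 * 0.5 * (hi - lo) / khat if khat > 0 else np.inf
            out[(pname, d)] = (lo, hi, rel)
    return out


def dwell_and_pdf(fit: PdaFitResult, r_grid=None):
    """Dwell times, state fractions and the equilibrium distance PDF.

    Dwell times are the reciprocal exit rates (``dwell_open = 1/k_closing``
    taking state 2 = open, state 1 = closed by the convention R1 < R2);
    dwells longer than 5 ms are censored (reported as ``> 5 ms``).  The
    PDF is the fraction-weighted sum of the state Gaussians with unit
    area.
    """
    m = fit.model
    if not fit.converged:
        raise ValueError("requires a converged fit")
    out = {"datasets": []}
    if r_grid is None:
        r_grid = np.linspace(10.0, 110.0, 1001)
    for d in range(m.n_datasets):
        if m.kind == "dynamic":
            k12, k21, a3 = m.k12[d], m.k21[d], m.A3[d]
            if k12 + k21 > 0:
                p1 = k21 / (k12 + k21)
            else:
                p1 = 0.5
            dwell1 = np.inf if k12 == 0 else 1.0 / k12
            dwell2 = np.inf if k21 == 0 else 1.0 / k21
            fr = [(1 - a3) * p1, (1 - a3) * (1 - p1), a3]
            dwells = {
                "state1_ms": dwell1, "state1_censored": dwell1 > DWELL_CENSOR_MS,
                "state2_ms": dwell2, "state2_censored": dwell2 > DWELL_CENSOR_MS,
            }
        else:
            fr = list(m.areas[d])
            dwells = {}
        pdf = np.zeros_like(r_grid)
        for f, R in zip(fr, (m.R1, m.R2, m.R_static)):
            if f <= 0 or R <= 0:
                continue
            s = max(m.sigma(R), 1e-6)
            pdf += f * np.exp(-0.5 * ((r_grid - R) / s) ** 2) / (
                s * np.sqrt(2 * np.pi))
        area = np.trapezoid(pdf, r_grid)
        if area > 0:
            pdf = pdf / area
        out["datasets"].append({"fractions": fr, "dwells": dwells,
                                "r_grid": r_grid, "pdf": pdf})
    return out
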