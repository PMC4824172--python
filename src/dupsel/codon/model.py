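"""Codon model fitting: M0, multi-ratio branch models, and M8/M8a site models.

The entry point is :class:`CodonModel`, a statsmodels-style model object
bound to one alignment/tree/partition; ``fit()`` runs bounded maximum
likelihood (L-BFGS-B on transformed parameters, seeded multi-start) and
returns a :class:`CodonFitResult` carrying MLEs, standard errors from the
observed information, lnL and the free-parameter count.

Model families
--------------
M0      one dN/dS ratio (omega) shared by all branches and sites.
BRANCH  one omega per branch class of a :class:`~dupsel.reconcile.BranchPartition`.
M8      beta-distributed site omegas (``ncat`` discrete classes, proportion
        p0) plus a positively selected class with omega_s >= 1.
M8A     as M8 with omega_s fixed at 1 (the neutral null).

Branch lengths are expected substitutions per codon site.  By default the
input tree's lengths are conditioned on; ``estimate_branch_lengths=True``
adds them to the free parameters (the usual workflow estimates them once
under M0 and fixes them for every other model on the same data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit, logsumexp

from ..alignments import CodonAlignment
from ..reconcile import BranchPartition
from ..trees import PhyloTree
from .likelihood import PruningEngine
from .rates import CodonEig, codon_eig, discretize_beta, prob_matrix

__all__ = [
    "CodonModelSpec",
    "CodonModel",
    "CodonFitResult",
    "fit_model",
    "log_likelihood",
    "site_class_mixture",
]

FAMILIES = ("M0", "BRANCH", "M8", "M8A")

_BOUNDS = {
    "kappa": (0.1, 20.0),
    "omega": (1e-4, 20.0),
    "p0": (1e-6, 1 - 1e-6),
    "p": (0.02, 99.0),
    "q": (0.02, 99.0),
    "omega_s": (1.0, 20.0),
    "bl": (1e-7, 50.0),
}

_DEFAULT_START = {"kappa": 2.0, "omega": 0.3, "p0": 0.9, "p": 1.0, "q": 2.0, "omega_s": 2.0}


def _kind(name: str) -> str:
    if name.startswith("omega_s"):
        return "omega_s"
    if name.startswith("omega"):
        return "omega"
    if name.startswith("bl:"):
        return "bl"
    return name


def _fwd(kind: str, v: float) -> float:
    if kind == "p0":
        return float(logit(v))
    if kind == "omega_s":
        return float(np.log(v - 1.0 + 1e-6))
    return float(np.log(v))


def _inv(kind: str, x: float) -> float:
    if kind == "p0":
        return float(expit(x))
    if kind == "omega_s":
        return float(np.exp(x) + 1.0 - 1e-6)
    return float(np.exp(x))


@dataclass
class CodonModelSpec:
    """Parameter bundle for a codon model (used for simulation and lnL evaluation)."""

    family: str = "M0"
    kappa: float = 2.0
    omega: float | Sequence[float] = 0.3
    freq_model: str = "F3X4"
    pi: np.ndarray | None = None
    p0: float = 0.9
    p: float = 1.0
    q: float = 2.0
    omega_s: float = 2.0
    ncat: int = 8

    def __post_init__(self):
        self.family = self.family.upper()
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.family == "M8A":
            self.omega_s = 1.0
        if self.family == "M8" and self.omega_s < 1.0:
            raise ValueError("M8 requires omega_s >= 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError("p0 must lie in [0, 1]")
        if np.any(np.asarray(self.omega, dtype=float) < 0):
            raise ValueError("omega must be >= 0")

    def omegas(self) -> np.ndarray:
        return np.atleast_1d(np.asarray(self.omega, dtype=float))


def site_class_mixture(
    p0: float, p: float, q: float, omega_s: float, ncat: int = 8
) -> tuple[np.ndarray, np.ndarray]:
    """Class omega values and weights for the M8/M8a site mixture."""
    vals, _ = discretize_beta(p, q, ncat)
    omegas = np.append(vals, omega_s)
    weights = np.append(np.full(ncat, p0 / ncat), 1.0 - p0)
    return omegas, weights


def branch_class_eigs(kappa: float, omegas: np.ndarray, pi: np.ndarray):
    """Per-class eigensystems; each class normalized to 1 sub/site/unit length."""
    eigs = [codon_eig(kappa, w, pi) for w in omegas]
    scales = np.array([e.rate for e in eigs])
    return eigs, scales


def site_class_eigs(kappa, p0, p, q, omega_s, pi, ncat=8):
    """Eigensystems for the site mixture, normalized by the mixture-mean rate."""
    omegas, weights = site_class_mixture(p0, p, q, omega_s, ncat)
    eigs = [codon_eig(kappa, w, pi) for w in omegas]
    rho = float(sum(wt * e.rate for wt, e in zip(weights, eigs)))
    return eigs, rho, omegas, weights


def _resolve_pi(alignment: CodonAlignment, freq_model: str, pi) -> np.ndarray:
    if pi is not None:
        pi = np.asarray(pi, dtype=float)
        return pi / pi.sum()
    fm = freq_model.upper()
    if fm == "UNIFORM":
        return np.full(61, 1.0 / 61)
    if fm == "F3X4":
        return alignment.f3x4_frequencies()
    if fm == "F61":
        return alignment.codon_frequencies(pseudocount=0.5)
    raise ValueError(f"unknown frequency model {freq_model!r}")


class CodonModel:
    """Maximum-likelihood codon model bound to an alignment and tree."""

    def __init__(
        self,
        alignment: CodonAlignment,
        tree: PhyloTree,
        partition: BranchPartition | None = None,
        family: str = "M0",
        freq_model: str = "F3X4",
        pi: np.ndarray | None = None,
        ncat: int = 8,
    ):
        family = family.upper()
        if family not in FAMILIES:
            raise ValueError(f"unknown model family {family!r}")
        if family == "BRANCH" and partition is None:
            raise ValueError("BRANCH models require a BranchPartition")
        if partition is not None and partition.tree is not tree:
            raise ValueError("partition was built on a different tree")
        self.family = family
        self.tree = tree
        self.alignment = alignment
        self.partition = partition if family == "BRANCH" else None
        self.n_classes = self.partition.n_classes if self.partition else 1
        self.ncat = ncat
        self.engine = PruningEngine(alignment, tree)
        self.pi = _resolve_pi(alignment, freq_model, pi)
        self.freq_model = "custom" if pi is not None else freq_model.upper()

    # -- parameters --------------------------------------------------------

    def param_names(self, estimate_branch_lengths: bool = False) -> list[str]:
        if self.family in ("M0", "BRANCH"):
            names = ["kappa"] + (
                ["omega"] if self.n_classes == 1 else [f"omega{i}" for i in range(self.n_classes)]
            )
        elif self.family == "M8":
            names = ["kappa", "p0", "p", "q", "omega_s"]
        else:  # M8A
            names = ["kappa", "p0", "p", "q"]
        if estimate_branch_lengths:
            names += [f"bl:{self.tree.names[v]}" for v in range(1, self.tree.n_nodes)]
        return names

    def _branch_lengths(self, params: Mapping[str, float]) -> np.ndarray:
        bl = self.tree.lengths.copy()
        for v in range(1, self.tree.n_nodes):
            key = f"bl:{self.tree.names[v]}"
            if key in params:
                bl[v] = params[key]
        return bl

    # -- likelihood --------------------------------------------------------

    def _pmats_branch(self, kappa, omegas, bl) -> dict[int, np.ndarray]:
        eigs, scales = branch_class_eigs(kappa, np.asarray(omegas, dtype=float), self.pi)
        classes = (
            self.partition.classes
            if self.partition is not None
            else np.zeros(self.tree.n_nodes, dtype=int)
        )
        cache: dict[tuple[int, float], np.ndarray] = {}
        pmats = {}
        for v in range(1, self.tree.n_nodes):
            key = (int(classes[v]), float(bl[v]))
            if key not in cache:
                cache[key] = prob_matrix(eigs[key[0]], key[1] / scales[key[0]])
            pmats[v] = cache[key]
        return pmats

    def _class_pattern_logliks(self, params: Mapping[str, float], bl) -> tuple[np.ndarray, np.ndarray]:
        """(n_class, n_patterns) site-class log-likelihoods and class weights."""
        omega_s = params.get("omega_s", 1.0)
        eigs, rho, _, weights = site_class_eigs(
            params["kappa"], params["p0"], params["p"], params["q"], omega_s, self.pi, self.ncat
        )
        out = np.empty((len(eigs), self.engine.n_patterns))
        for k, eig in enumerate(eigs):
            cache: dict[float, np.ndarray] = {}
            pmats = {}
            for v in range(1, self.tree.n_nodes):
                t = float(bl[v])
                if t not in cache:
                    cache[t] = prob_matrix(eig, t / rho)
                pmats[v] = cache[t]
            out[k] = self.engine.pattern_logliks(pmats, self.pi)
        return out, weights

    def loglike(self, params: Mapping[str, float]) -> float:
        """Log-likelihood at a full parameter dictionary."""
        bl = self._branch_lengths(params)
        if self.family in ("M0", "BRANCH"):
            if self.n_classes == 1:
                omegas = [params["omega"]]
            else:
                omegas = [params[f"omega{i}"] for i in range(self.n_classes)]
            pmats = self._pmats_branch(params["kappa"], omegas, bl)
            return self.engine.loglik(pmats, self.pi)
        class_ll, weights = self._class_pattern_logliks(params, bl)
        with np.errstate(divide="ignore"):
            logw = np.log(weights)
        site_ll = logsumexp(class_ll + logw[:, None], axis=0)
        return float(site_ll @ self.engine.counts)

    def loglike_spec(self, spec: CodonModelSpec) -> float:
        return self.loglike(self._params_from_spec(spec))

    def _params_from_spec(self, spec: CodonModelSpec) -> dict[str, float]:
        if spec.family != self.family:
            raise ValueError("spec family does not match model family")
        params = {"kappa": spec.kappa}
        if self.family in ("M0", "BRANCH"):
            om = spec.omegas()
            if self.n_classes == 1:
                params["omega"] = float(om[0])
            else:
                if len(om) != self.n_classes:
                    raise ValueError("omega vector length must equal partition class count")
                params.update({f"omega{i}": float(w) for i, w in enumerate(om)})
        else:
            params.update(p0=spec.p0, p=spec.p, q=spec.q)
            if self.family == "M8":
                params["omega_s"] = spec.omega_s
        return params

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        start: Mapping[str, float] | None = None,
        fixed: Mapping[str, float] | None = None,
        estimate_branch_lengths: bool = False,
        n_starts: int = 3,
        seed: int = 0,
        maxiter: int = 500,
        compute_se: bool = True,
    ) -> "CodonFitResult":
        """Bounded ML fit with seeded multi-start.

        ``fixed`` pins named parameters (e.g. ``{"omega": 0.12}``); ``start``
        overrides initial values (warm starts).  The first start uses the
        defaults/warm values, remaining starts are drawn log-uniformly
        within bounds from a seeded generator.
        """
        fixed = dict(fixed or {})
        names = self.param_names(estimate_branch_lengths)
        for key in fixed:
            if key not in names:
                raise ValueError(f"cannot fix unknown parameter {key!r}")
            kind = _kind(key)
            lo, hi = _BOUNDS[kind]
            if not lo <= fixed[key] <= hi:
                raise ValueError(f"fixed value for {key} outside bounds [{lo}, {hi}]")
        free = [n for n in names if n not in fixed]
        start = dict(start or {})

        def default(name: str) -> float:
            if name in start:
                return float(start[name])
            kind = _kind(name)
            if kind == "bl":
                v = self.tree.name_to_id[name[3:]]
                return max(float(self.tree.lengths[v]), _BOUNDS["bl"][0])
            return _DEFAULT_START[kind]

        def clip(name: str, v: float) -> float:
            lo, hi = _BOUNDS[_kind(name)]
            return float(np.clip(v, lo, hi))

        x0 = np.array([_fwd(_kind(n), clip(n, default(n))) for n in free])
        tbounds = [tuple(sorted((_fwd(_kind(n), b) for b in _BOUNDS[_kind(n)]))) for n in free]

        def unpack(x: np.ndarray) -> dict[str, float]:
            params = {n: _inv(_kind(n), xi) for n, xi in zip(free, x)}
            params.update(fixed)
            return params

        def negll(x: np.ndarray) -> float:
            try:
                return -self.loglike(unpack(x))
            except (FloatingPointError, np.linalg.LinAlgError):  # pragma: no cover
                return 1e12

        rng = np.random.default_rng(seed)
        best = None
        messages = []
        for s in range(max(1, n_starts)):
            if s == 0:
                xs = x0
            else:
                xs = np.array([lo + rng.uniform(0.05, 0.95) * (hi - lo) for lo, hi in tbounds])
            res = minimize(
                negll,
                xs,
                method="L-BFGS-B",
                jac="3-point",
                bounds=tbounds,
                options={
                    "maxiter": maxiter,
                    "ftol": 1e-12,
                    "gtol": 1e-7,
                    "finite_diff_rel_step": 1e-6,
                },
            )
            messages.append(str(res.message))
            if best is None or res.fun < best.fun:
                best = res
        params = unpack(best.x)
        llf = -float(best.fun)
        converged = bool(best.success)
        if not converged:
            warnings.warn(f"codon model fit did not converge: {messages[-1]}", RuntimeWarning)
        bse = {}
        if compute_se and free:
            bse = self._standard_errors(params, free)
        k = len(free)
        return CodonFitResult(
            model=self,
            params=params,
            free_names=free,
            fixed=fixed,
            llf=llf,
            k=k,
            bse=bse,
            converged=converged,
            n_starts=max(1, n_starts),
            messages=messages,
            estimated_branch_lengths=estimate_branch_lengths,
        )

    def _standard_errors(self, params: dict[str, float], free: list[str]) -> dict[str, float]:
        """SEs from the observed information (central differences, raw scale)."""
        theta = np.array([params[n] for n in free])
        steps = 1e-4 * np.maximum(np.abs(theta), 1e-3)

        def f(vec: np.ndarray) -> float:
            p = dict(params)
            p.update({n: v for n, v in zip(free, vec)})
            return self.loglike(p)

        m = len(free)
        h = np.zeros((m, m))
        f0 = f(theta)
        for i in range(m):
            ei = np.zeros(m)
            ei[i] = steps[i]
            h[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / steps[i] ** 2
            for j in range(i + 1, m):
                ej = np.zeros(m)
                ej[j] = steps[j]
                h[i, j] = h[j, i] = (
                    f(theta + ei + ej) - f(theta + ei - ej) - f(theta - ei + ej) + f(theta - ei - ej)
                ) / (4 * steps[i] * steps[j])
        try:
            cov = np.linalg.inv(-h)
            diag = np.diag(cov)
            se = np.where(diag > 0, np.sqrt(np.abs(diag)), np.nan)
        except np.linalg.LinAlgError:
            se = np.full(m, np.nan)
        return {n: float(s) for n, s in zip(free, se)}


@dataclass
class CodonFitResult:
    """MLEs, lnL and uncertainty for one fitted codon model."""

    model: CodonModel
    params: dict[str, float]
    free_names: list[str]
    fixed: dict[str, float]
    llf: float
    k: int
    bse: dict[str, float]
    converged: bool
    n_starts: int
    messages: list[str] = field(default_factory=list)
    estimated_branch_lengths: bool = False

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.llf

    @property
    def name(self) -> str:
        return self.model.family

    def refit(self, **kwargs) -> "CodonFitResult":
        """Refit warm-started at this result's MLEs."""
        kwargs.setdefault("fixed", self.fixed)
        kwargs.setdefault("estimate_branch_lengths", self.estimated_branch_lengths)
        return self.model.fit(start=self.params, **kwargs)

    def site_posteriors(self, method: str = "beb", grid_points: int = 5):
        from .sites import site_posteriors

        return site_posteriors(self, method=method, grid_points=grid_points)

    def to_dict(self) -> dict:
        return {
            "family": self.model.family,
            "lnL": self.llf,
            "k": self.k,
            "params": self.params,
            "se": self.bse,
            "fixed": self.fixed,
            "converged": self.converged,
            "n_starts": self.n_starts,
        }

    def summary(self) -> str:
        lines = [
            f"Codon model: {self.model.family}   lnL = {self.llf:.4f}   "
            f"k = {self.k}   AIC = {self.aic:.4f}",
            f"frequencies: {self.model.freq_model}   converged: {self.converged}",
            f"{'parameter':<14}{'estimate':>12}{'std err':>12}",
        ]
        for n in sorted(self.params, key=lambda s: (s.startswith("bl:"), s)):
            se = self.bse.get(n, np.nan)
            tag = " (fixed)" if n in self.fixed else ""
            lines.append(f"{n:<14}{self.params[n]:>12.5g}{se:>12.3g}{tag}")
        return "\n".join(lines)


def fit_model(
    alignment: CodonAlignment,
    tree: PhyloTree,
    partition: BranchPartition | None = None,
    family: str = "M0",
    freq_model: str = "F3X4",
    **fit_kwargs,
) -> CodonFitResult:
    """Functional wrapper: build a :class:`CodonModel` and fit it."""
    model = CodonModel(alignment, tree, partition, family=family, freq_model=freq_model)
    return model.fit(**fit_kwargs)


def log_likelihood(
    alignment: CodonAlignment,
    tree: PhyloTree,
    partition: BranchPartition | None,
    spec: CodonModelSpec,
) -> float:
    """Pruning log-likelihood of an alignment under a fully specified model."""
    model = CodonModel(
        alignment,
        tree,
        partition,
        family=spec.family,
        freq_model=spec.freq_model,
        pi=spec.pi,
        ncat=spec.ncat,
    )
    return model.loglike_spec(spec)
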