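"""Model comparison: likelihood-ratio tests, Akaike weights, and the
duplication-model and fixed-omega screening procedures.

Akaike weights w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2) with
Delta_i = AIC_i - min AIC give the relative support for each model within
a candidate set.  Nested pairs are compared by chi-square LRTs; the
alternative model is always warm-started at the null MLEs so the nesting
inequality lnL_alt >= lnL_null holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .alignments import CodonAlignment
from .codon.model import CodonFitResult, CodonModel
from .reconcile import BranchPartition, partition_branches
from .trees import PhyloTree

__all__ = [
    "lrt",
    "akaike_weights",
    "ModelComparison",
    "fixed_omega_comparison",
    "duplication_model_screen",
]


def lrt(lnl_null: float, lnl_alt: float, df: int) -> tuple[float, float]:
    """Likelihood-ratio statistic and chi-square p-value.

    The boundary caveat applies when the null pins a parameter at the edge
    of its space (e.g. M8a's omega_s = 1): the plain chi-square tail used
    here is then conservative.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if lnl_alt < lnl_null - 1e-6:
        raise ValueError(
            f"alternative lnL {lnl_alt} below null lnL {lnl_null}; "
            "warm-start the alternative at the null MLEs"
        )
    stat = max(0.0, 2.0 * (lnl_alt - lnl_null))
    return stat, float(chi2.sf(stat, df))


def akaike_weights(models: Sequence[tuple[float, int]]) -> np.ndarray:
    """Akaike weights from (lnL, k) pairs (max-subtracted for stability)."""
    if len(models) < 1:
        raise ValueError("at least one model is required")
    aic = np.array([2 * k - 2 * lnl for lnl, k in models], dtype=float)
    rel = -(aic - aic.min()) / 2.0
    w = np.exp(rel - rel.max())
    return w / w.sum()


@dataclass
class ModelComparison:
    """AIC/Akaike-weight table over a set of fitted models."""

    names: list[str]
    lnls: list[float]
    ks: list[int]
    fits: list[CodonFitResult] | None = None
    lrt_stat: float | None = None
    lrt_df: int | None = None
    lrt_p: float | None = None
    degenerate: bool = False
    note: str = ""
    weights: np.ndarray = field(init=False)

    def __post_init__(self):
        self.weights = akaike_weights(list(zip(self.lnls, self.ks)))

    @property
    def aic(self) -> np.ndarray:
        return 2 * np.asarray(self.ks, dtype=float) - 2 * np.asarray(self.lnls)

    @property
    def best(self) -> str:
        return self.names[int(np.argmax(self.weights))]

    def weight(self, name: str) -> float:
        return float(self.weights[self.names.index(name)])

    def to_frame(self) -> pd.DataFrame:
        aic = self.aic
        df = pd.DataFrame(
            {
                "model": self.names,
                "lnL": self.lnls,
                "k": self.ks,
                "AIC": aic,
                "dAIC": aic - aic.min(),
                # raw weights; round to 3 d.p. in the report layer
                "weight": self.weights,
            }
        )
        if self.lrt_p is not None:
            df.attrs["lrt"] = {"stat": self.lrt_stat, "df": self.lrt_df, "p": self.lrt_p}
        return df

    def to_dict(self) -> dict:
        out = {
            "models": [
                {"model": n, "lnL": l, "k": k, "weight": float(w)}
                for n, l, k, w in zip(self.names, self.lnls, self.ks, self.weights)
            ],
            "best": self.best,
            "degenerate": self.degenerate,
        }
        if self.lrt_p is not None:
            out["lrt"] = {"stat": self.lrt_stat, "df": self.lrt_df, "p": self.lrt_p}
        if self.note:
            out["note"] = self.note
        return out


def fixed_omega_comparison(
    alignment: CodonAlignment,
    tree: PhyloTree,
    omega_values: Mapping[str, float],
    freq_model: str = "F3X4",
    free_fit: CodonFitResult | None = None,
    **fit_kwargs,
) -> dict[str, ModelComparison]:
    """Compare the free M0 fit against M0 refits with omega pinned.

    For each named foreign omega (typically another subclade's estimate)
    the model is refitted with omega fixed (one fewer free parameter) and
    the {free, fixed} pair is compared by Akaike weights.
    """
    model = CodonModel(alignment, tree, family="M0", freq_model=freq_model)
    if free_fit is None:
        free_fit = model.fit(**fit_kwargs)
    out = {}
    for name, w in omega_values.items():
        fixed_fit = model.fit(
            start={"kappa": free_fit.params["kappa"]}, fixed={"omega": float(w)}, **fit_kwargs
        )
        out[name] = ModelComparison(
            names=["free", f"fixed@{name}"],
            lnls=[free_fit.llf, fixed_fit.llf],
            ks=[free_fit.k, fixed_fit.k],
            fits=[free_fit, fixed_fit],
            note=f"omega fixed at {w:g} ({name})",
        )
    return out


def duplication_model_screen(
    alignment: CodonAlignment,
    tree: PhyloTree,
    dup_nodes: Iterable[int | str],
    freq_model: str = "F3X4",
    branch_lengths: str = "fixed",
    **fit_kwargs,
) -> ModelComparison:
    """Akaike-weight screen of {M0, Immediate, All descendants}.

    The two branch models give the branches after each duplication event
    their own omega — only the event's child branches (Immediate) or every
    descendant branch (All descendants).  Branch models are warm-started
    at the M0 MLEs so lnL(M0) <= lnL(branch model).  With no duplication
    nodes both branch models collapse to M0 and the comparison is reported
    as degenerate (M0 only) rather than failing.

    ``branch_lengths='m0'`` estimates branch lengths once under M0 and
    conditions every model on those estimates; ``'fixed'`` (default)
    conditions on the input tree's lengths.
    """
    dup_nodes = list(dup_nodes)
    if branch_lengths not in ("fixed", "m0"):
        raise ValueError("branch_lengths must be 'fixed' or 'm0'")
    work_tree = tree
    if branch_lengths == "m0":
        m0_bl = CodonModel(alignment, tree, family="M0", freq_model=freq_model).fit(
            estimate_branch_lengths=True, compute_se=False, **fit_kwargs
        )
        work_tree = tree.copy()
        for v in range(1, tree.n_nodes):
            work_tree.lengths[v] = m0_bl.params[f"bl:{tree.names[v]}"]

    m0 = CodonModel(alignment, work_tree, family="M0", freq_model=freq_model).fit(**fit_kwargs)
    if not dup_nodes:
        return ModelComparison(
            names=["M0"],
            lnls=[m0.llf],
            ks=[m0.k],
            fits=[m0],
            degenerate=True,
            note="no duplication nodes: branch models collapse to M0",
        )
    names, lnls, ks, fits = ["M0"], [m0.llf], [m0.k], [m0]
    warm = {
        "kappa": m0.params["kappa"],
        "omega0": m0.params["omega"],
        "omega1": m0.params["omega"],
    }
    for label, mode in (("Immediate", "immediate"), ("All descendants", "all_descendants")):
        part = partition_branches(work_tree, dup_nodes, mode=mode)
        fit = CodonModel(
            alignment, work_tree, part, family="BRANCH", freq_model=freq_model
        ).fit(start=warm, **fit_kwargs)
        names.append(label)
        lnls.append(fit.llf)
        ks.append(fit.k)
        fits.append(fit)
    return ModelComparison(names=names, lnls=lnls, ks=ks, fits=fits)
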