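"""Per-subclade analysis pipeline and per-residue omega projection.

``run_subclade_analysis`` orchestrates, for each configured gene subclade:
LCA reconciliation against the species tree, the M0/Immediate/All-
descendants Akaike-weight screen, optional focal-event asymmetry LRTs,
the M8 vs M8a positive-selection scan with site posteriors, and — across
subclades — the completeness-filtered turnover fits with the Monte Carlo
rate-difference p-value matrix.  Every random step is seeded from the
config, so re-runs are byte-identical.
"""

from __future__ import annotations

import json
import logging
import os
from typing import Mapping

import numpy as np
import pandas as pd

from .alignments import read_codon_alignment
from .compare import duplication_model_screen, fixed_omega_comparison, lrt
from .codon.model import CodonModel
from .reconcile import partition_event, reconcile_lca
from .tables import filter_complete_species, read_count_table, read_domain_table, validate_domain_table
from .trees import parse_newick
from .turnover import GeneFamilyTurnover, resample_rate_pvalue

logger = logging.getLogger(__name__)

__all__ = ["project_site_omega", "run_subclade_analysis"]


def project_site_omega(
    site_table: pd.DataFrame,
    domains: pd.DataFrame,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Summarize per-residue omega over protein domain intervals.

    Residue i corresponds to codon column i (1-based).  Masked (trimmed)
    residues are excluded from the per-domain mean; the companion column
    ``mean_omega_structure`` applies the structure-mapping convention
    instead, counting masked residues as omega = 0 over all residues.
    """
    domains = validate_domain_table(domains, protein_length=int(site_table["site"].max()))
    omega = site_table.set_index("site")["mean_omega"]
    selected = site_table.set_index("site").get("selected")
    n_res = int(site_table["site"].max())
    if mask is None:
        mask = np.zeros(n_res, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    rows = []
    for _, d in domains.iterrows():
        sites = np.arange(d["start"], d["end"] + 1)
        m = mask[sites - 1]
        vals = omega.loc[sites].to_numpy(dtype=float)
        untrimmed = vals[~m]
        structure_vals = np.where(m, 0.0, vals)
        rows.append(
            {
                "domain": d["domain"],
                "n_sites": int(len(sites)),
                "n_masked": int(m.sum()),
                "mean_omega": float(untrimmed.mean()) if len(untrimmed) else float("nan"),
                "mean_omega_structure": float(structure_vals.mean()),
                "n_selected": int(selected.loc[sites][~m].sum()) if selected is not None else 0,
            }
        )
    return pd.DataFrame(rows)


def _load_config(config) -> dict:
    if isinstance(config, (str, os.PathLike)):
        with open(config) as fh:
            return json.load(fh)
    return dict(config)


def _stage(report: dict, subclade: str, stage: str, payload):
    report.setdefault("subclades", {}).setdefault(subclade, {})[stage] = payload


def run_subclade_analysis(config, outdir: str | os.PathLike) -> dict:
    """Run the full duplication-aware analysis described by ``config``.

    Config keys (JSON file or dict): ``species_tree`` (Newick path),
    ``subclades`` (list of {name, alignment, gene_tree, leaf_map,
    [domains], [mask], [focal_events]}), ``count_tables`` (name -> TSV
    path), ``seed``, and optional ``options`` ({nrep, freq_model,
    site_scan, fit: {n_starts, ...}}).  Writes report.json plus TSV tables
    under ``outdir`` and returns the report dict.  Any stage failure raises
    a stage-tagged RuntimeError; results of completed stages are preserved
    in report.json.
    """
    cfg = _load_config(config)
    os.makedirs(outdir, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    opts = cfg.get("options", {})
    nrep = int(opts.get("nrep", 1000))
    freq_model = opts.get("freq_model", "F3X4")
    fit_kwargs = dict(opts.get("fit", {}))
    fit_kwargs.setdefault("seed", seed)
    report: dict = {"seed": seed, "options": {"nrep": nrep, "freq_model": freq_model}}

    def save_tsv(name: str, df: pd.DataFrame):
        df.to_csv(os.path.join(outdir, name), sep="\t", index=False)

    def finalize():
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, default=_jsonable)

    try:
        species_tree = parse_newick(_read(cfg["species_tree"]), dated=True)
        m0_fits: dict[str, float] = {}
        for sub in cfg.get("subclades", []):
            name = sub["name"]
            stage = f"{name}:load"
            try:
                aln = read_codon_alignment(sub["alignment"], sub.get("mask"))
                gene_tree = parse_newick(_read(sub["gene_tree"]))
                leaf_map = _read_leaf_map(sub["leaf_map"])

                stage = f"{name}:reconcile"
                rec = reconcile_lca(gene_tree, species_tree, leaf_map)
                save_tsv(f"{name}.reconciliation.tsv", rec.to_frame())
                _stage(report, name, "reconcile", {"duplications": rec.duplication_names})

                stage = f"{name}:screen"
                screen = duplication_model_screen(
                    aln, gene_tree, rec.duplication_names, freq_model=freq_model, **fit_kwargs
                )
                save_tsv(f"{name}.screen.tsv", screen.to_frame())
                _stage(report, name, "screen", screen.to_dict())
                m0 = screen.fits[0]
                m0_fits[name] = m0
                _stage(report, name, "m0", m0.to_dict())

                stage = f"{name}:asymmetry"
                asym = []
                for event in sub.get("focal_events", []):
                    for mode in ("immediate", "all_descendants"):
                        sym_part = partition_event(gene_tree, event, mode, symmetric=True)
                        asym_part = partition_event(gene_tree, event, mode, symmetric=False)
                        warm = {"kappa": m0.params["kappa"]}
                        sym_fit = CodonModel(
                            aln, gene_tree, sym_part, family="BRANCH", freq_model=freq_model
                        ).fit(start=warm, **fit_kwargs)
                        warm_a = dict(sym_fit.params)
                        warm_a["omega2"] = warm_a["omega1"]
                        asym_fit = CodonModel(
                            aln, gene_tree, asym_part, family="BRANCH", freq_model=freq_model
                        ).fit(start=warm_a, **fit_kwargs)
                        stat, p = lrt(sym_fit.llf, asym_fit.llf, df=1)
                        asym.append(
                            {
                                "event": event,
                                "mode": mode,
                                "lnL_symmetric": sym_fit.llf,
                                "lnL_asymmetric": asym_fit.llf,
                                "lrt_stat": stat,
                                "lrt_p": p,
                                "omegas": {
                                    lbl: asym_fit.params[f"omega{i}"]
                                    for i, lbl in enumerate(asym_part.labels)
                                },
                            }
                        )
                if asym:
                    _stage(report, name, "asymmetry", asym)

                if opts.get("site_scan", True):
                    stage = f"{name}:sites"
                    m8a = CodonModel(aln, gene_tree, family="M8A", freq_model=freq_model).fit(
                        **fit_kwargs
                    )
                    warm = dict(m8a.params)
                    warm["omega_s"] = 1.5
                    m8_model = CodonModel(aln, gene_tree, family="M8", freq_model=freq_model)
                    m8 = m8_model.fit(start=warm, **fit_kwargs)
                    if m8.llf < m8a.llf:
                        # interior start lost to the boundary null; retry at it
                        boundary = m8_model.fit(
                            start={**m8a.params, "omega_s": 1.0}, **fit_kwargs
                        )
                        if boundary.llf > m8.llf:
                            m8 = boundary
                    # omega_s = 1 makes M8a a boundary case of M8; equality holds
                    # there, so round residual optimizer slack up to the null
                    stat, p = lrt(m8a.llf, max(m8.llf, m8a.llf), df=1)
                    sites = m8.site_posteriors(method=opts.get("beb_method", "beb"))
                    save_tsv(f"{name}.sites.tsv", sites)
                    _stage(
                        report,
                        name,
                        "site_scan",
                        {
                            "m8a": m8a.to_dict(),
                            "m8": m8.to_dict(),
                            "lrt": {"stat": stat, "df": 1, "p": p,
                                    "note": "boundary null: chi-square is conservative"},
                            "n_selected": int(sites["selected"].sum()),
                        },
                    )
                    if "domains" in sub:
                        stage = f"{name}:domains"
                        domains = read_domain_table(sub["domains"])
                        proj = project_site_omega(sites, domains, aln.mask)
                        save_tsv(f"{name}.domains.tsv", proj)
                        _stage(report, name, "domains", proj.to_dict(orient="records"))
            except Exception as exc:
                finalize()
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

        # cross-subclade fixed-omega comparisons
        if len(m0_fits) > 1:
            stage = "fixed_omega"
            for name, fit in m0_fits.items():
                others = {
                    o: f.params["omega"] for o, f in m0_fits.items() if o != name
                }
                sub_cfg = next(s for s in cfg["subclades"] if s["name"] == name)
                comps = fixed_omega_comparison(
                    read_codon_alignment(sub_cfg["alignment"]),
                    parse_newick(_read(sub_cfg["gene_tree"])),
                    others,
                    freq_model=freq_model,
                    free_fit=fit,
                    **fit_kwargs,
                )
                _stage(report, name, "fixed_omega", {o: c.to_dict() for o, c in comps.items()})

        # turnover
        if cfg.get("count_tables"):
            stage = "turnover"
            tables = {n: read_count_table(p) for n, p in cfg["count_tables"].items()}
            filtered = {
                n: filter_complete_species(t, tables.values()) for n, t in tables.items()
            }
            retained = list(next(iter(filtered.values())).columns)
            report["turnover"] = {
                "n_species_retained": len(retained),
                "n_species_total": len(next(iter(tables.values())).columns),
                "fits": {},
            }
            turnover_tree = (
                species_tree
                if set(retained) == set(species_tree.leaf_names)
                else species_tree.prune(retained)
            )
            fits = {}
            for n, t in filtered.items():
                res = GeneFamilyTurnover(t, turnover_tree).fit()
                fits[n] = res
                report["turnover"]["fits"][n] = res.to_dict()
            names = list(fits)
            pmat = pd.DataFrame(index=names, columns=names, dtype=float)
            for ia, a in enumerate(names):
                for ib, b in enumerate(names):
                    if a == b:
                        continue
                    pmat.loc[a, b] = resample_rate_pvalue(
                        turnover_tree,
                        lam_fixed=fits[a].lam,
                        lam_observed_other=fits[b].lam,
                        nfam=len(filtered[b]),
                        nrep=nrep,
                        seed=seed + 101 * ia + ib,
                    )
            pmat.index.name = "lam_fixed_at"
            pmat.to_csv(os.path.join(outdir, "turnover_pvalues.tsv"), sep="\t")
            report["turnover"]["pvalues"] = {
                a: {b: (None if pd.isna(v) else float(v)) for b, v in row.items()}
                for a, row in pmat.iterrows()
            }
    finally:
        finalize()
    return report


def _read(path_or_text: str) -> str:
    if os.path.exists(str(path_or_text)):
        with open(path_or_text) as fh:
            return fh.read()
    return str(path_or_text)


def _read_leaf_map(source) -> dict[str, str]:
    if isinstance(source, Mapping):
        return dict(source)
    text = _read(source)
    out = {}
    for line in text.strip().splitlines():
        gene, species = line.split("\t")[:2]
        out[gene.strip()] = species.strip()
    return out


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON serializable: {type(obj)}")
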