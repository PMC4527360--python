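"""Per-feature split-plot ANOVA screening for vintage and producer effects.

Sampling in a multi-year vineyard survey is randomized only within a year,
so year (vintage) and replicate act as whole-plot factors and producer
(vineyard) as the subplot factor. The additive model is

    y = mu + year + replicate + wholeplot_error(year x replicate)
        + producer + residual

with the year-by-replicate interaction stratum serving as the whole-plot
error: year and replicate are tested against it, producer against the
residual. No year-by-producer interaction is included by default (the
screening model names only the three factors); it can be added behind a
flag and is then tested against the residual.

Sums of squares are the sequential decomposition, which on the balanced
(or near-balanced) year x replicate x producer design equals the usual
cell-means decomposition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import StudyDesign

__all__ = ["split_plot_anova", "anova_screen"]


def _group_means_ss(y, labels, grand):
    ss = 0.0
    for lev in pd.unique(labels):
        sel = labels == lev
        ss += sel.sum() * (y[sel].mean() - grand) ** 2
    return ss


def split_plot_anova(
    values,
    design: StudyDesign,
    year_col: str = "vintage",
    rep_col: str = "replicate",
    producer_col: str = "vineyard",
    interaction: bool = False,
) -> pd.DataFrame:
    """Split-plot ANOVA of one response over the design.

    Returns a table with one row per stratum (year, replicate,
    wholeplot_error, producer, optional year:producer, residual) carrying
    df, SS, MS and — where an error stratum exists — F and p.
    """
    y = np.asarray(values, dtype=float)
    year = design.factor(year_col)
    rep = design.factor(rep_col)
    prod = design.factor(producer_col)
    n = len(y)
    if n != len(year):
        raise ValueError("response and design length differ")
    a, b, g = len(pd.unique(year)), len(pd.unique(rep)), len(pd.unique(prod))
    # every year x replicate whole plot must be observed
    cells = pd.crosstab(pd.Series(year), pd.Series(rep))
    if (cells.values == 0).any():
        raise ValueError("empty year x replicate cell; split-plot strata undefined")
    if b < 2:
        raise ValueError(
            "a single replicate level leaves no whole-plot error stratum"
        )
    grand = y.mean()
    ss_total = float(np.sum((y - grand) ** 2))
    ss_year = _group_means_ss(y, year, grand)
    ss_rep = _group_means_ss(y, rep, grand)
    # whole-plot (year x replicate) stratum, beyond the two main effects
    ss_cells = 0.0
    for yl in pd.unique(year):
        for rl in pd.unique(rep):
            sel = (year == yl) & (rep == rl)
            ss_cells += sel.sum() * (y[sel].mean() - grand) ** 2
    ss_wp = ss_cells - ss_year - ss_rep
    ss_prod = _group_means_ss(y, prod, grand)
    rows = [
        ("year", a - 1, ss_year),
        ("replicate", b - 1, ss_rep),
        ("wholeplot_error", (a - 1) * (b - 1), ss_wp),
        ("producer", g - 1, ss_prod),
    ]
    if interaction:
        ss_yp = 0.0
        for yl in pd.unique(year):
            for pl in pd.unique(prod):
                sel = (year == yl) & (prod == pl)
                if sel.any():
                    ss_yp += sel.sum() * (y[sel].mean() - grand) ** 2
        ss_yp -= ss_year + ss_prod
        rows.append(("year:producer", (a - 1) * (g - 1), ss_yp))
    df_used = sum(r[1] for r in rows)
    ss_used = sum(r[2] for r in rows)
    rows.append(("residual", n - 1 - df_used, ss_total - ss_used))
    tab = pd.DataFrame(rows, columns=["factor", "df", "SS"]).set_index("factor")
    tab["MS"] = np.where(tab["df"] > 0, tab["SS"] / tab["df"].replace(0, 1), np.nan)
    tab.loc[tab["df"] == 0, "MS"] = np.nan
    tab["F"] = np.nan
    tab["p"] = np.nan
    degenerate = ss_total <= 1e-12 * max(1.0, abs(grand)) ** 2
    ms_wp = tab.loc["wholeplot_error", "MS"]
    ms_res = tab.loc["residual", "MS"]
    df_wp = tab.loc["wholeplot_error", "df"]
    df_res = tab.loc["residual", "df"]

    def _test(factor, ms_err, df_err):
        if degenerate or not np.isfinite(ms_err) or ms_err <= 0 or df_err <= 0:
            return
        F = tab.loc[factor, "MS"] / ms_err
        tab.loc[factor, "F"] = F
        tab.loc[factor, "p"] = stats.f.sf(F, tab.loc[factor, "df"], df_err)

    _test("year", ms_wp, df_wp)
    _test("replicate", ms_wp, df_wp)
    _test("producer", ms_res, df_res)
    if interaction:
        _test("year:producer", ms_res, df_res)
    tab.attrs["degenerate"] = bool(degenerate)
    tab.attrs["producer_untestable"] = bool(df_res <= 0)
    return tab


def anova_screen(
    table,
    design: StudyDesign,
    alpha: float = 0.05,
    fdr: bool = False,
    interaction: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Split-plot ANOVA per feature; fraction significant per factor.

    Returns (per-feature results, summary). The per-feature table carries
    p_year and p_producer (Benjamini-Hochberg adjusted when ``fdr``);
    features whose ANOVA fails (for instance constant response) are flagged
    and the run continues.
    """
    X = table.values
    feats = table.features
    recs = []
    for j, f in enumerate(feats):
        try:
            tab = split_plot_anova(X[:, j], design, interaction=interaction)
            recs.append(
                {
                    "feature": f,
                    "p_year": tab.loc["year", "p"],
                    "p_producer": tab.loc["producer", "p"],
                    "degenerate": tab.attrs["degenerate"],
                    "error": "",
                }
            )
        except ValueError as exc:
            recs.append(
                {
                    "feature": f,
                    "p_year": np.nan,
                    "p_producer": np.nan,
                    "degenerate": True,
                    "error": str(exc),
                }
            )
    res = pd.DataFrame(recs).set_index("feature")
    if fdr:
        from statsmodels.stats.multitest import multipletests

        for col in ("p_year", "p_producer"):
            ok = res[col].notna()
            if ok.any():
                res.loc[ok, col] = multipletests(
                    res.loc[ok, col].to_numpy(), method="fdr_bh"
                )[1]
    ok = res["p_year"].notna() & res["p_producer"].notna()
    n_ok = int(ok.sum())
    summary = {
        "n_features": len(feats),
        "n_tested": n_ok,
        "alpha": alpha,
        "frac_year_significant": float((res.loc[ok, "p_year"] < alpha).mean())
        if n_ok
        else float("nan"),
        "frac_producer_significant": float(
            (res.loc[ok, "p_producer"] < alpha).mean()
        )
        if n_ok
        else float("nan"),
    }
    return res, summary
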