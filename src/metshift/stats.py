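"""Per-metabolite statistics: two-way ANOVA, triglyceride regression,
reaction-norm classification and PCA sanity checks.

The ANOVA models each metabolite's log abundance on diet, reaction-norm
class and their interaction with Type-II sums of squares (the design is
unbalanced); the post hoc contrast is a two-sample t between the two
extreme reaction-norm classes. Raw p-values are always accompanied by
Benjamini-Hochberg q-values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .io import AbundanceTable, SampleAnnotation


def _meta_frame(meta: list[SampleAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in meta],
            "diet": [m.diet for m in meta],
            "genotype": [m.genotype for m in meta],
            "reaction_norm": [m.reaction_norm for m in meta],
            "triglyceride": [m.triglyceride for m in meta],
        }
    ).set_index("sample_id")


def anova_two_way(table: AbundanceTable, meta: list[SampleAnnotation]) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA (diet x reaction norm) per metabolite.

    Returns, per metabolite, F and p for the diet, reaction-norm and
    interaction terms (Type-II sums of squares), the post hoc t between the
    N_gt_HF and N_lt_HF classes, and BH q-values per term.
    """
    md = _meta_frame(meta).loc[table.sample_ids]
    for factor in ("diet", "reaction_norm"):
        levels = md[factor].dropna().unique()
        if len(levels) < 2:
            raise ValueError(f"factor {factor!r} has a single level")
    rows = []
    for met in table.metabolite_ids:
        df = pd.DataFrame(
            {"y": table.values[met], "diet": md["diet"], "rn": md["reaction_norm"]}
        ).dropna()
        fit = smf.ols("y ~ C(diet) * C(rn)", data=df).fit()
        tab = sm.stats.anova_lm(fit, typ=2)
        gt = df.loc[df["rn"] == "N_gt_HF", "y"]
        lt = df.loc[df["rn"] == "N_lt_HF", "y"]
        tstat, tp = stats.ttest_ind(gt, lt, equal_var=False)
        rows.append(
            {
                "metabolite": met,
                "F_diet": tab.loc["C(diet)", "F"],
                "p_diet": tab.loc["C(diet)", "PR(>F)"],
                "F_rn": tab.loc["C(rn)", "F"],
                "p_rn": tab.loc["C(rn)", "PR(>F)"],
                "F_interaction": tab.loc["C(diet):C(rn)", "F"],
                "p_interaction": tab.loc["C(diet):C(rn)", "PR(>F)"],
                "t_posthoc": float(tstat),
                "p_posthoc": float(tp),
            }
        )
    out = pd.DataFrame(rows).set_index("metabolite")
    for term in ("diet", "rn", "interaction", "posthoc"):
        out[f"q_{term}"] = multipletests(out[f"p_{term}"], method="fdr_bh")[1]
    return out


def triglyceride_regression(
    table: AbundanceTable, meta: list[SampleAnnotation]
) -> pd.DataFrame:
    """OLS of each metabolite's log abundance on triglyceride level.

    Reports slope, Pearson r (signed), p, and BH q per metabolite.
    """
    md = _meta_frame(meta).loc[table.sample_ids]
    trig = md["triglyceride"].astype(float)
    if trig.isna().any():
        raise ValueError("triglyceride missing for some samples")
    if trig.nunique() == 1:
        raise ValueError("triglyceride is constant; regression undefined")
    rows = []
    for met in table.metabolite_ids:
        y = table.values[met]
        ok = y.notna()
        res = stats.linregress(trig[ok], y[ok])
        rows.append(
            {
                "metabolite": met,
                "slope": res.slope,
                "r": res.rvalue,
                "p": res.pvalue,
            }
        )
    out = pd.DataFrame(rows).set_index("metabolite")
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def assign_reaction_norm(
    trig_nd: float, trig_hfd: float, threshold_fraction: float = 0.25
) -> str:
    """Class a genotype's triglyceride reaction norm by the 25% rule.

    N_lt_HF when the high-fat value exceeds the normal-diet value by at
    least the threshold fraction; N_gt_HF for the reverse; "zero" when the
    change is below threshold in both directions.
    """
    if trig_nd <= 0 or trig_hfd <= 0:
        raise ValueError("triglyceride values must be positive")
    f = threshold_fraction
    if trig_hfd >= (1.0 + f) * trig_nd:
        return "N_lt_HF"
    if trig_nd >= (1.0 + f) * trig_hfd:
        return "N_gt_HF"
    return "zero"


def pca_scores(
    table: AbundanceTable,
    subset_metabolites: list[str] | None = None,
    scale: bool = True,
    n_components: int | None = None,
) -> dict:
    """Centered (optionally scaled) PCA of a metabolite subset.

    Returns sample scores, loadings and per-component variance fractions.
    """
    cols = subset_metabolites if subset_metabolites is not None else table.metabolite_ids
    if len(cols) < 2:
        raise ValueError("need at least 2 metabolites")
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    X = table.values[cols].values.astype(float)
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    k = n_components or min(X.shape)
    pca = PCA(n_components=min(k, min(X.shape)))
    scores = pca.fit_transform(X)
    comp_names = [f"PC{i+1}" for i in range(scores.shape[1])]
    return {
        "scores": pd.DataFrame(scores, index=table.sample_ids, columns=comp_names),
        "loadings": pd.DataFrame(pca.components_.T, index=cols, columns=comp_names),
        "variance_fraction": pd.Series(pca.explained_variance_ratio_, index=comp_names),
    }


def importance_significance_overlap(
    importance: pd.DataFrame, anova: pd.DataFrame, term: str = "diet", alpha: float = 0.05
) -> dict:
    """Contrast the top-|S| important metabolites with the significant set S.

    S is the set with raw p < alpha for the term; the comparison takes the
    same number of top metabolites by scaled importance, reporting how many
    significant metabolites the importance ranking misses.
    """
    sig = set(anova.index[anova[f"p_{term}"] < alpha])
    k = len(sig)
    top = set(importance.sort_values("scaled", ascending=False).index[:k])
    return {
        "n_significant": k,
        "n_top_important": len(top),
        "n_shared": len(sig & top),
        "significant_not_important": sorted(sig - top),
    }
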