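"""Structure-corrected functional allele-state association scan.

Per gene, the binary functional/LoF allele state across ecotypes is
regressed on an environmental or phenotypic predictor (drought-timing
index, flowering time, latitude, minimum temperature) by logistic
regression, with population structure controlled by the top principal
components of the ecotype kinship (identity-in-state) matrix as fixed
covariates.  P values are Bonferroni-adjusted within each predictor's scan,
and genes are classified by slope sign among significant hits:
positive-slope drought hits are "spring" (LoF found in spring-drought
environments), negative "summer"; flowering hits split into "later" /
"earlier" the same way.

A single random permutation of the genotype-matrix rows (ecotype labels),
which preserves every gene's allele frequency, provides the negative
control: with real structure broken, the scan should report no significant
genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


class AssociationError(ValueError):
    pass


def kinship(background: np.ndarray) -> np.ndarray:
    """Identity-in-state kinship from a haploid 0/1 background genotype matrix.

    ``background`` is (n_ecotypes, n_markers).  Similarity between two
    ecotypes is the fraction of markers with identical alleles, in [0, 1]
    with 1 on the diagonal.  Constant markers carry no information and are
    dropped with a warning.
    """
    G = np.asarray(background, dtype=float)
    if G.ndim != 2 or G.shape[0] < 2 or G.shape[1] < 1:
        raise AssociationError("need >= 2 ecotypes and >= 1 marker")
    variable = G.std(axis=0) > 0
    if not variable.all():
        warnings.warn(
            f"dropping {int((~variable).sum())} constant markers", stacklevel=2
        )
        G = G[:, variable]
    if G.shape[1] == 0:
        raise AssociationError("all markers constant")
    m = G.shape[1]
    shared = G @ G.T + (1 - G) @ (1 - G).T
    return shared / m


@dataclass
class StructureCovariates:
    """Top kinship principal components used as fixed covariates."""

    components: np.ndarray  # (n_ecotypes, k)
    variance_explained: np.ndarray  # (k,)


def structure_pcs(K: np.ndarray, k: int = 3) -> StructureCovariates:
    """Principal components of the kinship matrix (top-k eigenvectors).

    Variance explained is each eigenvalue over the trace.  Eigenvector signs
    are normalized so the first nonzero loading is positive.
    """
    K = np.asarray(K, dtype=float)
    n = K.shape[0]
    if K.shape != (n, n) or not np.allclose(K, K.T, atol=1e-8):
        raise AssociationError("kinship must be square symmetric")
    if k >= n:
        raise AssociationError(f"k={k} must be < number of ecotypes {n}")
    eigvals, eigvecs = np.linalg.eigh(K)
    order = np.argsort(eigvals)[::-1][:k]
    vals, vecs = eigvals[order], eigvecs[:, order]
    for j in range(vecs.shape[1]):
        nz = np.nonzero(np.abs(vecs[:, j]) > 1e-12)[0]
        if nz.size and vecs[nz[0], j] < 0:
            vecs[:, j] = -vecs[:, j]
    return StructureCovariates(
        components=vecs, variance_explained=vals / np.trace(K)
    )


def _fit_logistic(y: np.ndarray, X: np.ndarray):
    """IRLS logistic fit; returns (beta, se, p, converged, separated)."""
    model = sm.GLM(y, X, family=sm.families.Binomial())
    separated = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=100, tol=1e-8)
        beta, se = res.params, res.bse
        converged = bool(getattr(res, "converged", True))
    except Exception:
        return np.nan, np.nan, np.nan, False, True
    # diverging coefficients or exploding SEs mark (quasi-)separation
    if np.abs(beta[1]) > 30 or se[1] > 1e3 or not np.isfinite(se[1]):
        separated = True
    z = beta[1] / se[1] if se[1] > 0 else np.nan
    p = 2 * stats.norm.sf(abs(z))
    return beta[1], se[1], p, converged, separated


def logistic_scan(
    states: pd.DataFrame,
    predictor: pd.Series,
    covariates: StructureCovariates | None = None,
    predictor_name: str = "predictor",
) -> pd.DataFrame:
    """Per-gene logistic regression of allele state on a predictor.

    ``states`` is the ecotype x gene 0/1/NaN functional-state matrix;
    ``predictor`` is aligned on ecotype index.  Ecotypes missing either the
    state or the predictor are dropped pairwise per gene.  Returns a per-gene
    table (beta, se, p_raw, n, converged, separated); separated or
    non-converged fits carry NaN P rather than a fabricated value.
    """
    pred = predictor.reindex(states.index)
    if pred.dropna().nunique() <= 1:
        raise AssociationError("predictor is constant")
    pcs = covariates.components if covariates is not None else None
    rows = []
    pred_arr = pred.to_numpy(dtype=float)
    for gene_id in states.columns:
        y_all = states[gene_id].to_numpy(dtype=float)
        keep = np.isfinite(y_all) & np.isfinite(pred_arr)
        y, x = y_all[keep], pred_arr[keep]
        X = np.column_stack([np.ones(keep.sum()), x])
        if pcs is not None:
            X = np.column_stack([X, pcs[keep]])
        if y.sum() == 0 or y.sum() == len(y):
            rows.append((gene_id, np.nan, np.nan, np.nan, int(keep.sum()), False, True))
            continue
        beta, se, p, converged, separated = _fit_logistic(y, X)
        if separated or not converged:
            p = np.nan
        rows.append((gene_id, beta, se, p, int(keep.sum()), converged, separated))
    out = pd.DataFrame(
        rows, columns=["gene_id", "beta", "se", "p_raw", "n", "converged", "separated"]
    ).set_index("gene_id")
    out.insert(0, "predictor", predictor_name)
    return out


def bonferroni(results: pd.DataFrame, m: int | None = None) -> pd.DataFrame:
    """Bonferroni adjustment: p_adj = min(1, p_raw * m) within the scan family."""
    if m is None:
        m = len(results)
    if m < 1:
        raise AssociationError("m must be >= 1")
    out = results.copy()
    out["p_adj"] = np.minimum(1.0, out["p_raw"] * m)
    return out


def classify_genes(
    drought: pd.DataFrame,
    flowering: pd.DataFrame,
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Two-axis gene classification from the drought and flowering scans.

    Significant (P < alpha, strict) positive-slope drought genes are
    "spring", negative "summer"; flowering genes split into "later" /
    "earlier"; everything else is "none".  By default significance uses the
    Bonferroni-adjusted P (``use_adjusted=False`` switches to raw P).
    """
    genes = drought.index
    if not genes.equals(flowering.index):
        raise AssociationError("drought and flowering scans cover different genes")
    col = "p_adj" if use_adjusted else "p_raw"

    def axis(res, pos, neg):
        p = res[col]
        sig = p.notna() & (p < alpha)
        lab = np.where(
            sig & (res["beta"] > 0), pos, np.where(sig & (res["beta"] < 0), neg, "none")
        )
        return lab

    out = pd.DataFrame(index=genes)
    out["drought_class"] = axis(drought, "spring", "summer")
    out["flowering_class"] = axis(flowering, "later", "earlier")
    return out


def scan_all_predictors(
    states: pd.DataFrame,
    predictors: pd.DataFrame,
    covariates: StructureCovariates | None = None,
    alpha: float = 0.05,
) -> dict:
    """Run the per-gene scan for every predictor column, with Bonferroni."""
    return {
        name: bonferroni(
            logistic_scan(states, predictors[name], covariates, predictor_name=name)
        )
        for name in predictors.columns
    }


def permute_states(states: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Randomly permute ecotype labels (matrix rows) once.

    Per-gene allele frequencies are preserved exactly; the link between
    genotype and any per-ecotype predictor is broken.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(states))
    permuted = states.iloc[perm].copy()
    permuted.index = states.index
    return permuted


def permutation_scan(
    states: pd.DataFrame,
    predictors: pd.DataFrame,
    covariates: StructureCovariates | None,
    seed: int,
    alpha: float = 0.05,
) -> tuple[dict, int]:
    """Full scan on a label-permuted matrix; returns results and the number
    of genes significant after Bonferroni on any predictor."""
    permuted = permute_states(states, seed)
    results = scan_all_predictors(permuted, predictors, covariates, alpha)
    sig = np.zeros(len(states.columns), dtype=bool)
    for res in results.values():
        sig |= (res["p_adj"].to_numpy() < alpha) & np.isfinite(res["p_adj"].to_numpy())
    return results, int(sig.sum())


def cross_predictor_regression(
    p_flowering: pd.Series,
    p_drought: pd.Series,
    p_latitude: pd.Series,
    p_mintemp: pd.Series,
) -> tuple[pd.DataFrame, float]:
    """Does drought timing predict flowering associations beyond geography?

    Multiple linear regression of -log10 P(flowering) on -log10 P of the
    drought-timing, latitude and minimum-temperature scans over the shared
    gene set.  Zero P values are floored at the smallest positive float
    before the log.  Also returns r^2 between the drought and flowering
    -log10 P vectors.
    """
    df = pd.DataFrame(
        {
            "flowering": p_flowering,
            "drought": p_drought,
            "latitude": p_latitude,
            "min_temp": p_mintemp,
        }
    ).dropna()
    if len(df) < 4:
        raise AssociationError("need >= 4 genes with all four P values")
    tiny = np.finfo(float).tiny
    logs = -np.log10(df.clip(lower=tiny))
    X = sm.add_constant(logs[["drought", "latitude", "min_temp"]])
    fit = sm.OLS(logs["flowering"], X).fit()
    table = pd.DataFrame(
        {"coef": fit.params, "se": fit.bse, "t": fit.tvalues, "p": fit.pvalues}
    )
    r2 = float(np.corrcoef(logs["drought"], logs["flowering"])[0, 1] ** 2)
    return table, r2


def qq_diagnostics(p_values) -> pd.DataFrame:
    """Expected-vs-observed -log10 P quantiles plus genomic inflation.

    Expected quantiles are -log10((i - 0.5) / n) for sorted P.  The returned
    frame carries a ``lambda_gc`` attribute: median observed chi-square
    (1 df, from P) over the median of the null chi-square distribution.
    """
    p = np.asarray(pd.Series(p_values).dropna(), dtype=float)
    if p.size < 1:
        raise AssociationError("need at least one P value")
    p_sorted = np.sort(p)
    n = p.size
    expected = (np.arange(1, n + 1) - 0.5) / n
    out = pd.DataFrame(
        {
            "expected_neglog10": -np.log10(expected),
            "observed_neglog10": -np.log10(np.clip(p_sorted, np.finfo(float).tiny, 1)),
        }
    )
    chisq = stats.chi2.isf(np.clip(p, np.finfo(float).tiny, 1), df=1)
    out.attrs["lambda_gc"] = float(np.median(chisq) / stats.chi2.ppf(0.5, df=1))
    return out
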