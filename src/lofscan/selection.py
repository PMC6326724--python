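"""Selection signatures and candidate-gene statistics.

Covers: the overlap test between drought-timing and flowering-time gene
classes (co-association enrichment), the correlation between scan P values,
the direction-bias goodness-of-fit test, unique-allele/frequency contrasts
between associated and non-associated genes, McDonald-Kreitman-style
PN/PS-DN/DS counting against an outgroup, and the LoF burden regression of
flowering time on the per-ecotype count of LoF alleles across candidate
genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from Bio.Seq import Seq


class SelectionError(ValueError):
    pass


def chisq_5050(k: int, n: int) -> tuple[float, float]:
    """Goodness-of-fit chi-square of ``k`` of ``n`` against a 50:50 split.

    Shared kernel of the direction-bias test and the knockout sign test:
    chi2 = 2 * (k - n/2)^2 / (n/2), P from the 1-df chi-square distribution.
    No continuity correction.
    """
    if n < 1:
        raise SelectionError("need at least one observation")
    expected = n / 2.0
    chi2 = 2.0 * (k - expected) ** 2 / expected
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Overlap / direction


@dataclass
class OverlapTable:
    """Co-association of drought and flowering classifications.

    2x2 cross-classification of genes by "associated with drought timing"
    and "associated with flowering time"; concordant co-associations are
    summer&earlier plus spring&later, discordant the two cross pairings.
    ``fold_enrichment`` is observed concordant over the expected both-axes
    cell under independence.
    """

    observed: np.ndarray  # 2x2 [drought yes/no] x [flowering yes/no]
    expected: np.ndarray
    chi2: float
    p: float
    n_concordant: int
    n_discordant: int
    fold_enrichment: float
    reliable: bool


def fold_enrichment(observed: float, expected: float) -> float:
    """Observed over expected co-associated gene count."""
    if expected <= 0:
        raise SelectionError("expected count must be positive")
    return observed / expected


def overlap_test(classes: pd.DataFrame) -> OverlapTable:
    """Chi-square test of independence between the two association axes.

    ``classes`` needs ``drought_class`` in {spring, summer, none} and
    ``flowering_class`` in {later, earlier, none}.  Cells with expected
    count 0 make the chi-square unreliable; this is reported, not hidden.
    """
    d = classes["drought_class"] != "none"
    f = classes["flowering_class"] != "none"
    obs = np.array(
        [
            [int((d & f).sum()), int((d & ~f).sum())],
            [int((~d & f).sum()), int((~d & ~f).sum())],
        ],
        dtype=float,
    )
    n = obs.sum()
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / n
    reliable = bool((expected > 0).all())
    with np.errstate(divide="ignore", invalid="ignore"):
        cells = np.where(expected > 0, (obs - expected) ** 2 / expected, 0.0)
    chi2 = float(cells.sum())
    concordant = int(
        ((classes["drought_class"] == "summer") & (classes["flowering_class"] == "earlier")).sum()
        + ((classes["drought_class"] == "spring") & (classes["flowering_class"] == "later")).sum()
    )
    discordant = int((d & f).sum()) - concordant
    return OverlapTable(
        observed=obs,
        expected=expected,
        chi2=chi2,
        p=float(stats.chi2.sf(chi2, df=1)),
        n_concordant=concordant,
        n_discordant=discordant,
        fold_enrichment=concordant / expected[0, 0] if expected[0, 0] > 0 else np.nan,
        reliable=reliable,
    )


def pvalue_correlation(p_a: pd.Series, p_b: pd.Series) -> float:
    """Squared Pearson correlation of log10-transformed P values (shared genes)."""
    df = pd.DataFrame({"a": p_a, "b": p_b}).dropna()
    if len(df) < 3:
        raise SelectionError("need >= 3 genes with both P values")
    tiny = np.finfo(float).tiny
    la, lb = np.log10(df["a"].clip(lower=tiny)), np.log10(df["b"].clip(lower=tiny))
    return float(np.corrcoef(la, lb)[0, 1] ** 2)


def direction_bias_test(classes: pd.DataFrame) -> dict:
    """Is the association direction biased toward spring-drought / later flowering?

    Counts genes associated with spring drought and/or later flowering vs
    genes associated with summer drought and/or earlier flowering, and tests
    against 50:50.  Genes falling in both direction groups are excluded.
    """
    spring_later = (classes["drought_class"] == "spring") | (
        classes["flowering_class"] == "later"
    )
    summer_earlier = (classes["drought_class"] == "summer") | (
        classes["flowering_class"] == "earlier"
    )
    both = spring_later & summer_earlier
    a = int((spring_later & ~both).sum())
    b = int((summer_earlier & ~both).sum())
    n = a + b
    if n == 0:
        raise SelectionError("no associated genes to test")
    chi2, p = chisq_5050(a, n)
    return {
        "n_spring_later": a,
        "n_summer_earlier": b,
        "n_excluded_both": int(both.sum()),
        "chi2": chi2,
        "p": p,
    }


# ---------------------------------------------------------------------------
# Unique-allele and frequency contrasts


def unique_allele_contrasts(
    allele_table: pd.DataFrame,
    classes: pd.DataFrame,
    pseudocount: float = 0.5,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Contrast associated vs non-associated genes on three allele statistics.

    Two-sided t-tests (Welch by default) on log10-transformed per-gene
    values of: number of unique LoF alleles, global LoF frequency, and mean
    frequency per specific allele.  Zero counts get ``pseudocount`` before
    the log.  Positive selection for LoF predicts fewer unique alleles each
    at higher frequency in associated genes, at similar global frequency.
    """
    assoc = (classes["drought_class"] != "none") | (classes["flowering_class"] != "none")
    assoc = assoc.reindex(allele_table.index)
    rows = []
    for col in ("n_unique", "lof_freq", "mean_allele_freq"):
        raw = allele_table[col].astype(float)
        vals = np.log10(raw.where(raw > 0, pseudocount))
        a = vals[assoc.fillna(False)]
        b = vals[~assoc.fillna(True)]
        if len(a) < 2 or len(b) < 2:
            raise SelectionError(f"need >= 2 genes per group for {col}")
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        rows.append((col, float(a.mean()), float(b.mean()), float(t), float(p), len(a), len(b)))
    return pd.DataFrame(
        rows,
        columns=["statistic", "mean_assoc_log10", "mean_other_log10", "t", "p", "n_assoc", "n_other"],
    ).set_index("statistic")


# ---------------------------------------------------------------------------
# McDonald-Kreitman counting


@dataclass
class MkCounts:
    """Polymorphism/divergence counts for one gene vs an outgroup."""

    gene_id: str
    pn: int
    ps: int
    dn: int
    ds: int

    @property
    def pn_ps(self) -> float:
        return self.pn / self.ps if self.ps else np.nan

    @property
    def dn_ds(self) -> float:
        return self.dn / self.ds if self.ds else np.nan


def _major(values: list) -> str:
    counts = pd.Series(values).value_counts()
    return counts.index[0]


def mk_counts(
    ingroup: dict, outgroup_seq: str, gene_id: str = "gene"
) -> MkCounts:
    """Count PN/PS (ingroup polymorphism) and DN/DS (fixed divergence).

    All sequences must be aligned to equal length; codons containing a gap
    in any sequence are removed first.  Per nucleotide site: if the ingroup
    varies the site is polymorphic (each non-major allele classified
    synonymous/nonsynonymous by translating the ingroup-major codon with the
    allele substituted); if the ingroup is monomorphic and differs from the
    outgroup it is a fixed difference.  Sites both polymorphic and divergent
    count as polymorphic only.
    """
    seqs = {k: v.upper() for k, v in ingroup.items()}
    out = outgroup_seq.upper()
    lengths = {len(s) for s in seqs.values()} | {len(out)}
    if len(lengths) != 1:
        raise SelectionError(f"{gene_id}: aligned sequences differ in length")
    L = lengths.pop()
    if L % 3 != 0:
        raise SelectionError(f"{gene_id}: alignment length {L} not divisible by 3")
    rows = list(seqs.values())
    keep_codons = [
        c
        for c in range(L // 3)
        if all("-" not in s[3 * c : 3 * c + 3] for s in rows + [out])
    ]
    strip = lambda s: "".join(s[3 * c : 3 * c + 3] for c in keep_codons)
    rows = [strip(s) for s in rows]
    out = strip(out)
    ref0 = rows[0]
    if "*" in str(Seq(ref0[: len(ref0) - 3]).translate()):
        raise SelectionError(f"{gene_id}: internal stop codon in reference frame")

    pn = ps = dn = ds = 0
    n_sites = len(out)
    for site in range(n_sites):
        codon_idx, within = divmod(site, 3)
        in_alleles = [s[site] for s in rows]
        major = _major(in_alleles)
        major_codon = _major([s[3 * codon_idx : 3 * codon_idx + 3] for s in rows])
        aa_major = str(Seq(major_codon).translate())

        def aa_with(base):
            codon = major_codon[:within] + base + major_codon[within + 1 :]
            return str(Seq(codon).translate())

        others = sorted(set(in_alleles) - {major})
        if others:  # polymorphic site
            for allele in others:
                if aa_with(allele) == aa_major:
                    ps += 1
                else:
                    pn += 1
        elif out[site] != major:  # ingroup monomorphic, diverged
            if aa_with(out[site]) == aa_major:
                ds += 1
            else:
                dn += 1
    return MkCounts(gene_id=gene_id, pn=pn, ps=ps, dn=dn, ds=ds)


def mk_counts_from_fasta(path, outgroup_id: str, gene_id: str | None = None) -> MkCounts:
    """MK counts from a multi-FASTA alignment; ``outgroup_id`` names the outgroup."""
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if outgroup_id not in seqs:
        raise SelectionError(f"outgroup {outgroup_id!r} not in alignment")
    out = seqs.pop(outgroup_id)
    return mk_counts(seqs, out, gene_id=gene_id or str(path))


def mk_group_comparison(groups: dict, equal_var: bool = False) -> pd.DataFrame:
    """Two-sided t-tests of PN/PS and DN/DS between gene groups.

    ``groups`` maps group name -> list of :class:`MkCounts`.  Genes with an
    undefined ratio (zero denominator) are excluded and counted.  Each pair
    of groups is compared for each ratio.
    """
    ratios = {}
    excluded = {}
    for name, counts in groups.items():
        pnps = [c.pn_ps for c in counts if c.ps > 0]
        dnds = [c.dn_ds for c in counts if c.ds > 0]
        ratios[name] = {"pn_ps": pnps, "dn_ds": dnds}
        excluded[name] = {
            "pn_ps": len(counts) - len(pnps),
            "dn_ds": len(counts) - len(dnds),
        }
    rows = []
    names = list(groups)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            for ratio in ("pn_ps", "dn_ds"):
                va, vb = ratios[a][ratio], ratios[b][ratio]
                if len(va) < 2 or len(vb) < 2:
                    raise SelectionError(
                        f"group {a if len(va) < 2 else b} has < 2 genes with defined {ratio}"
                    )
                t, p = stats.ttest_ind(va, vb, equal_var=equal_var)
                rows.append(
                    (
                        ratio,
                        a,
                        b,
                        float(np.mean(va)),
                        float(np.mean(vb)),
                        float(t),
                        float(p),
                        excluded[a][ratio] + excluded[b][ratio],
                    )
                )
    return pd.DataFrame(
        rows,
        columns=["ratio", "group_a", "group_b", "mean_a", "mean_b", "t", "p", "n_undefined"],
    )


# ---------------------------------------------------------------------------
# Burden regression


def burden_regression(
    states: pd.DataFrame,
    flowering: pd.Series,
    candidate_genes: list,
) -> dict:
    """Flowering time vs per-ecotype LoF count over candidate genes.

    The burden is the total number of LoF alleles an ecotype carries across
    the candidate genes (missing calls count as functional).  Fits the
    linear model and an augmented quadratic model; the F-test compares them.
    Returns slope (days per LoF allele), its SE, r^2, P, and the quadratic
    F and P.
    """
    import statsmodels.api as sm

    genes = [g for g in candidate_genes if g in states.columns]
    if len(genes) < 2:
        raise SelectionError("need >= 2 candidate genes present in the matrix")
    burden = states[genes].sum(axis=1, skipna=True)
    df = pd.DataFrame({"burden": burden, "flowering": flowering}).dropna()
    if len(df) < 10:
        raise SelectionError("need >= 10 ecotypes")
    if df["burden"].nunique() <= 1:
        raise SelectionError("LoF burden is constant across ecotypes")
    X1 = sm.add_constant(df[["burden"]])
    fit1 = sm.OLS(df["flowering"], X1).fit()
    X2 = X1.assign(burden_sq=df["burden"] ** 2)
    fit2 = sm.OLS(df["flowering"], X2).fit()
    f_stat, f_p, _ = fit2.compare_f_test(fit1)
    return {
        "slope_days_per_allele": float(fit1.params["burden"]),
        "slope_se": float(fit1.bse["burden"]),
        "slope_p": float(fit1.pvalues["burden"]),
        "r2": float(fit1.rsquared),
        "n": int(len(df)),
        "quadratic_f": float(f_stat),
        "quadratic_p": float(f_p),
    }
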