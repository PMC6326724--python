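"""T-DNA knockout experiment analysis.

Plants are grown in a shelf-stratified randomized design; flowering is
recorded as days after planting to the emergence of the first open flower.
Per-line adjusted (least-squares) means come from a mixed model with line as
a fixed effect and shelf and tray as random intercepts (REML), so shelf and
tray placement cannot bias line comparisons.  The collective prediction —
that knockouts of candidate genes flower later than the wild type — is then
tested by a 50:50 goodness-of-fit chi-square on the sign of each line's
difference from the wild-type adjusted mean.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .selection import chisq_5050


class KnockoutError(ValueError):
    pass


REQUIRED_COLUMNS = ("line", "shelf", "tray", "days")


def _validate(table: pd.DataFrame, wild_type: str) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise KnockoutError(f"experiment table missing column {col!r}")
    if (table["days"] <= 0).any():
        raise KnockoutError("days-to-flower must be positive")
    if wild_type not in set(table["line"]):
        raise KnockoutError(f"wild type {wild_type!r} absent from experiment")
    isolated = [
        str(shelf)
        for shelf, grp in table.groupby("shelf")
        if grp["line"].nunique() < 2
    ]
    if isolated:
        raise KnockoutError(
            f"design not connected: shelves with a single line: {', '.join(isolated)}"
        )
    return table


def adjusted_line_means(
    table: pd.DataFrame, wild_type: str = "Col-0", nested_trays: bool = True
) -> pd.DataFrame:
    """Block-adjusted per-line mean flowering times.

    Line is fixed; shelf is a random intercept and tray a nested (default)
    or crossed variance component, fitted by REML.  Adjusted means are the
    fixed-effect line estimates at average block levels.  If the block
    variance estimates collapse to zero (or the fit is degenerate) the model
    reduces to plain arithmetic line means; the ``note`` column records
    this.  Single-replicate lines are kept but flagged.

    Returns one row per line: adjusted_mean, se, n_reps, diff_from_wt,
    sign ('+', '-', '0'), note.
    """
    import statsmodels.formula.api as smf

    table = _validate(table.copy(), wild_type)
    table["line"] = table["line"].astype(str)
    if nested_trays:
        table["tray_id"] = table["shelf"].astype(str) + ":" + table["tray"].astype(str)
    else:
        table["tray_id"] = table["tray"].astype(str)
    lines = sorted(table["line"].unique())
    note = ""
    means, ses = {}, {}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                f"days ~ C(line, Treatment(reference='{wild_type}'))",
                data=table,
                groups="shelf",
                re_formula="1",
                vc_formula={"tray": "0 + C(tray_id)"},
            )
            fit = model.fit(reml=True)
        block_var = float(fit.cov_re.iloc[0, 0]) + float(sum(fit.vcomp))
        degenerate = not fit.converged or block_var < 1e-10
    except (np.linalg.LinAlgError, ValueError):
        degenerate = True
    if degenerate:
        note = "zero or degenerate block variance; plain line means reported"
        grouped = table.groupby("line")["days"]
        for line in lines:
            means[line] = float(grouped.mean()[line])
            n = int(grouped.count()[line])
            sd = float(grouped.std(ddof=1)[line]) if n > 1 else np.nan
            ses[line] = sd / np.sqrt(n) if n > 1 else np.nan
    else:
        intercept = float(fit.params["Intercept"])
        for line in lines:
            if line == wild_type:
                means[line] = intercept
                ses[line] = float(fit.bse["Intercept"])
            else:
                key = f"C(line, Treatment(reference='{wild_type}'))[T.{line}]"
                means[line] = intercept + float(fit.params[key])
                ses[line] = float(fit.bse[key])
    wt_mean = means[wild_type]
    rows = []
    counts = table.groupby("line")["days"].count()
    for line in lines:
        diff = means[line] - wt_mean
        sign = "0" if diff == 0 else ("+" if diff > 0 else "-")
        line_note = note
        if counts[line] == 1:
            line_note = (line_note + "; " if line_note else "") + "single replicate"
        rows.append((line, means[line], ses[line], int(counts[line]), diff, sign, line_note))
    return pd.DataFrame(
        rows,
        columns=["line", "adjusted_mean", "se", "n_reps", "diff_from_wt", "sign", "note"],
    ).set_index("line")


def sign_test(line_means: pd.DataFrame, wild_type: str = "Col-0") -> dict:
    """Do knockout lines flower later than the wild type more often than chance?

    Counts lines whose adjusted mean exceeds the wild type's and tests the
    later/earlier split against 50:50 (chi-square, 1 df).  Exact ties are
    excluded and reported.
    """
    others = line_means.drop(index=wild_type, errors="ignore")
    if len(others) < 1:
        raise KnockoutError("need at least one non-wild-type line")
    later = int((others["sign"] == "+").sum())
    earlier = int((others["sign"] == "-").sum())
    ties = int((others["sign"] == "0").sum())
    n = later + earlier
    if n == 0:
        raise KnockoutError("all lines tie the wild type exactly")
    chi2, p = chisq_5050(later, n)
    return {
        "n_lines": len(others),
        "n_later": later,
        "n_earlier": earlier,
        "n_ties_excluded": ties,
        "chi2": chi2,
        "p": p,
    }
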