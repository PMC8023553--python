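"""Class propensities, the correction factor, and descriptive statistics.

Because residue types are not equally distributed across the three surface
classes, per-class feature averages are corrected by a propensity factor

    C_factor(class, residue) = f_class(residue) / f_total(residue)

the ratio of the residue type's frequency within the class to its frequency
over all residues.  Selected feature columns are multiplied by the factor
of their (class, residue) cell; relASA is exempt by default.  Summaries are
reported per (feature, class, residue) as Q1/Q2/Q3 (linear interpolation),
mean and sample standard deviation, with residues ordered by increasing
Kyte–Doolittle hydropathy, and classes are compared per feature with
pairwise independent t-tests and one-way ANOVA.
"""

from __future__ import annotations

import logging
import warnings
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger("dimerfeat")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Named residue subsets used for aggregate statistics (one-letter codes).
RESIDUE_SUBSETS: dict[str, frozenset[str]] = {
    "charged": frozenset("DEKR"),
    "positive": frozenset("KR"),
    "negative": frozenset("DE"),
    "polar": frozenset("STNQYH"),
    "non_polar": frozenset("AVILMFW"),
    "aromatic": frozenset("FWY"),
    "excluded": frozenset("CGP"),
    "gas": frozenset("GAS"),
}


def kyte_doolittle() -> dict[str, float]:
    """Kyte–Doolittle hydropathy values keyed by one-letter code."""
    text = resources.files("dimerfeat.data").joinpath("kyte_doolittle.tsv").read_text()
    out = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, val = line.split()
        out[aa] = float(val)
    return out


def _to_one(resn: str) -> str:
    return THREE_TO_ONE.get(resn, resn) if len(resn) == 3 else resn


def propensities(class_labels, residue_names) -> pd.DataFrame:
    """Per-(class, residue) frequencies and correction factors.

    ``f_class`` is the residue's frequency within the class, ``f_total`` its
    frequency over the entire dataset; ``c_factor = f_class / f_total``.
    Residue types absent from the whole dataset get a missing factor, not 0.
    """
    labels = pd.Series(list(class_labels), name="class")
    resn = pd.Series([_to_one(r) for r in residue_names], name="residue")
    if len(labels) == 0:
        raise ValueError("propensities of an empty dataset are undefined")
    if len(labels) != len(resn):
        raise ValueError("class labels and residue names differ in length")

    total = resn.value_counts(normalize=True)
    rows = []
    for cls, group in resn.groupby(labels):
        f_class = group.value_counts(normalize=True)
        for aa in ONE_TO_THREE:
            fc = float(f_class.get(aa, 0.0))
            ft = float(total.get(aa, 0.0))
            rows.append({
                "class": cls, "residue": aa,
                "f_class": fc, "f_total": ft,
                "c_factor": fc / ft if ft > 0 else np.nan,
            })
    return pd.DataFrame(rows)


def correction_lookup(prop: pd.DataFrame) -> dict[tuple[str, str], float]:
    return {(r["class"], r["residue"]): r["c_factor"] for _, r in prop.iterrows()}


def correct_features(
    feature_table: pd.DataFrame,
    prop: pd.DataFrame,
    features_to_correct: list[str],
    class_col: str = "class",
    residue_col: str = "resn",
    exempt: tuple[str, ...] = ("rel_asa",),
) -> pd.DataFrame:
    """Multiply selected feature columns by each row's class/residue factor.

    Columns listed in ``exempt`` (relASA by default) are never corrected.
    Rows whose factor is missing pass through unchanged and are flagged in a
    ``correction_missing`` column.
    """
    lookup = correction_lookup(prop)
    out = feature_table.copy()
    keys = list(zip(out[class_col], out[residue_col].map(_to_one)))
    factors = np.array([lookup.get(k, np.nan) for k in keys])
    out["correction_missing"] = np.isnan(factors)
    applied = np.where(np.isnan(factors), 1.0, factors)
    for col in features_to_correct:
        if col in exempt:
            continue
        out[col] = out[col] * applied
    return out


def summarize(
    feature_table: pd.DataFrame,
    group_by: list[str],
    features: list[str],
    residue_col: str = "resn",
) -> pd.DataFrame:
    """Q1/Q2/Q3, mean, sample SD and n per feature and group.

    Quartiles use linear interpolation between order statistics; the SD is
    the n−1 sample estimate (missing for singleton groups).  Output rows are
    ordered by increasing Kyte–Doolittle hydropathy when the grouping
    includes the residue column.
    """
    kd = kyte_doolittle()
    rows = []
    for keys, group in feature_table.groupby(group_by, dropna=False, sort=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        for feat in features:
            vals = pd.to_numeric(group[feat], errors="coerce").dropna().to_numpy()
            if len(vals) == 0:
                warnings.warn(f"group {keys}: feature {feat!r} has no values, row dropped")
                continue
            q1, q2, q3 = np.percentile(vals, [25, 50, 75])
            rows.append({
                **dict(zip(group_by, keys)),
                "feature": feat,
                "q1": q1, "q2": q2, "q3": q3,
                "avg": float(vals.mean()),
                "std": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                "n": int(len(vals)),
            })
    out = pd.DataFrame(rows)
    if residue_col in group_by and not out.empty:
        out["_kd"] = out[residue_col].map(lambda r: kd.get(_to_one(r), np.nan))
        out = out.sort_values(["feature", "_kd"] if "feature" in out else ["_kd"],
                              kind="stable").drop(columns="_kd").reset_index(drop=True)
    return out


def group_tests(
    feature_table: pd.DataFrame,
    features: list[str],
    class_col: str = "class",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Pairwise independent t-tests and one-way ANOVA across classes.

    Raw p-values are reported (no multiple-testing correction by default);
    :func:`benjamini_hochberg` can be applied to the result.  Groups with
    fewer than two observations yield missing p-values with a reason.
    """
    classes = [c for c in feature_table[class_col].dropna().unique()]
    if len(classes) < 2:
        raise ValueError("group tests need at least two classes")
    rows = []
    for feat in features:
        samples = {}
        for cls in classes:
            v = pd.to_numeric(
                feature_table.loc[feature_table[class_col] == cls, feat],
                errors="coerce").dropna().to_numpy()
            samples[cls] = v
        for i, c1 in enumerate(classes):
            for c2 in classes[i + 1:]:
                if len(samples[c1]) < 2 or len(samples[c2]) < 2:
                    rows.append({"feature": feat, "comparison": f"{c1} vs {c2}",
                                 "test": "t", "statistic": np.nan, "p_value": np.nan,
                                 "note": "insufficient n"})
                    continue
                t, p = sps.ttest_ind(samples[c1], samples[c2], equal_var=equal_var)
                rows.append({"feature": feat, "comparison": f"{c1} vs {c2}",
                             "test": "t", "statistic": float(t), "p_value": float(p),
                             "note": ""})
        usable = [v for v in samples.values() if len(v) >= 2]
        if len(usable) >= 2:
            f, p = sps.f_oneway(*usable)
            rows.append({"feature": feat, "comparison": "ANOVA " + " | ".join(classes),
                         "test": "anova", "statistic": float(f), "p_value": float(p),
                         "note": ""})
        else:
            rows.append({"feature": feat, "comparison": "ANOVA", "test": "anova",
                         "statistic": np.nan, "p_value": np.nan,
                         "note": "insufficient groups"})
    return pd.DataFrame(rows)


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH-adjusted q-values (monotone step-up), NaNs passed through."""
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = len(pv)
    if m == 0:
        return q
    order = np.argsort(pv)
    ranked = pv[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


def min_max_scale(values: pd.Series | np.ndarray) -> np.ndarray:
    """Scale to [0, 1]; constant input maps to 0."""
    v = np.asarray(values, dtype=float)
    lo, hi = np.nanmin(v), np.nanmax(v)
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)
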