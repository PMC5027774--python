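"""Morphological analysis: summaries, discriminant functions, identification.

Works on a per-specimen table of meristic counts (fin rays, vertebrae, gill
rakers, dermal plicae), raw measurements in mm plus standard length (SL),
and yes/no qualitative characters. Measurements are standardized to percent
of standard length (``value * 100 / SL``) before any statistics.

The multi-group discriminant function analysis (canonical variates) solves
the generalized eigenproblem of the between-group scatter ``B`` against the
pooled within-group scatter ``W``: the discriminant functions are the
eigenvectors of ``W^-1 B``, at most ``min(groups - 1, variables)`` of them.
Separation is tested with Wilks' lambda (Bartlett's chi-square
approximation) and homogeneity of group covariances with Box's M.

A rule-based identification key assigns genus (premaxilla protrusibility,
prevomer/vomerine teeth, dermal plicae count, pectoral-fin length in %SL)
and then species within each genus from qualitative states and count/range
evidence, reporting per-character evidence and a matched/evaluated
confidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = [
    "MERISTIC_COLS",
    "MEASUREMENT_COLS",
    "QUALITATIVE_COLS",
    "COMPOSITE_MERISTICS",
    "REFERENCE_CHARACTERS",
    "MorphTable",
    "DFAResult",
    "standardize_percent_sl",
    "summarize_characters",
    "select_dfa_variables",
    "discriminant_analysis",
    "loo_classification_rate",
    "identification_key",
    "default_key_config",
    "IdentificationResult",
]

MERISTIC_COLS = ["DP", "DR", "AR", "PR", "CR", "UR", "LR", "GR", "PV", "CV",
                 "TV"]
MEASUREMENT_COLS = ["BDD", "BDA", "BWD", "HL", "SNL", "OD", "IW", "UJL",
                    "CPD", "CPL", "PPL", "PDL", "PAL", "PFL", "DFBL", "AFBL",
                    "CFL", "DFH", "AFH"]
QUALITATIVE_COLS = ["MDAS", "BCOP", "PCP", "VTP", "DSSS", "BSTC", "SBCF",
                    "SADF"]
#: Composite counts are sums of their parts and excluded from DFA.
COMPOSITE_MERISTICS = {"GR": ("UR", "LR"), "TV": ("PV", "CV")}

# Published reference values for the four NE Atlantic sand lance species:
# per character (mean, SD, min, max); measurements in %SL, SL in mm.
# Qualitative states are "yes"/"no"; "unknown" = not clearly detectable.
REFERENCE_CHARACTERS: dict[str, dict] = {
    "Ammodytes marinus": {
        "SL_mm": (136.7, 29.7, 61.2, 193.0),
        "meristics": {
            "DP": (143.1, 2.6, 140, 150), "DR": (59.1, 1.4, 56, 62),
            "AR": (29.5, 0.8, 28, 31), "PR": (13.6, 0.6, 12, 15),
            "CR": (15.0, 0.0, 15, 15), "UR": (5.0, 0.2, 5, 6),
            "LR": (18.6, 0.8, 18, 20), "PV": (42.9, 0.7, 42, 44),
            "CV": (26.7, 0.5, 26, 28),
        },
        "measurements": {
            "BDD": (9.1, 1.3, 5.9, 11.1), "BDA": (8.1, 1.2, 4.9, 10.1),
            "BWD": (5.3, 0.7, 4.1, 6.4), "HL": (20.0, 1.1, 17.6, 22.6),
            "SNL": (5.7, 0.3, 5.1, 6.1), "OD": (3.2, 0.5, 2.7, 4.4),
            "IW": (2.4, 0.3, 2.0, 3.5), "UJL": (6.7, 1.0, 4.6, 10.3),
            "CPD": (2.6, 0.2, 2.2, 2.9), "CPL": (4.1, 0.5, 3.2, 5.6),
            "PPL": (18.6, 1.0, 16.6, 21.7), "PDL": (25.3, 1.0, 23.5, 28.1),
            "PAL": (64.9, 1.1, 63.4, 66.8), "PFL": (9.9, 0.7, 8.6, 11.9),
            "DFBL": (69.8, 1.4, 66.6, 72.0), "AFBL": (30.5, 1.0, 28.9, 32.4),
            "CFL": (10.1, 0.7, 8.3, 11.5), "DFH": (4.7, 0.7, 3.6, 6.0),
            "AFH": (4.7, 0.8, 2.6, 6.2),
        },
        "qualitative": {"MDAS": "yes", "BCOP": "yes", "PCP": "yes",
                        "VTP": "no", "DSSS": "no", "BSTC": "no",
                        "SBCF": "no", "SADF": "no"},
    },
    "Ammodytes tobianus": {
        "SL_mm": (134.1, 7.7, 121.5, 146.4),
        "meristics": {
            "DP": (128.5, 3.0, 123, 135), "DR": (52.8, 1.1, 51, 55),
            "AR": (27.8, 1.3, 25, 30), "PR": (13.0, 0.2, 12, 13),
            "CR": (15.0, 0.0, 15, 15), "UR": (5.0, 0.0, 5, 5),
            "LR": (20.0, 0.0, 20, 20), "PV": (38.1, 1.4, 36, 41),
            "CV": (25.1, 0.6, 24, 26),
        },
        "measurements": {
            "BDD": (9.5, 0.8, 8.3, 11.9), "BDA": (9.4, 0.8, 7.3, 10.4),
            "BWD": (6.0, 0.9, 4.0, 7.6), "HL": (19.6, 0.8, 18.4, 21.4),
            "SNL": (5.4, 0.3, 5.1, 6.0), "OD": (3.0, 0.3, 2.6, 3.5),
            "IW": (2.4, 0.2, 2.1, 2.9), "UJL": (6.4, 0.4, 5.4, 7.0),
            "CPD": (3.0, 0.1, 2.8, 3.2), "CPL": (4.3, 0.5, 3.5, 5.4),
            "PPL": (18.6, 1.1, 14.8, 20.4), "PDL": (25.4, 1.0, 24.0, 27.3),
            "PAL": (63.7, 1.9, 60.3, 67.0), "PFL": (10.4, 0.5, 9.4, 11.4),
            "DFBL": (69.2, 1.1, 66.9, 70.8), "AFBL": (31.6, 1.9, 26.7, 33.4),
            "CFL": (10.3, 0.7, 9.0, 12.0), "DFH": (4.8, 0.6, 3.9, 6.1),
            "AFH": (4.8, 0.5, 3.4, 5.8),
        },
        "qualitative": {"MDAS": "yes", "BCOP": "yes", "PCP": "yes",
                        "VTP": "no", "DSSS": "no", "BSTC": "yes",
                        "SBCF": "yes", "SADF": "yes"},
    },
    "Hyperoplus immaculatus": {
        "SL_mm": (251.4, 15.0, 220.4, 270.1),
        "meristics": {
            "DP": (187.8, 5.4, 179, 196), "DR": (60.1, 0.6, 59, 61),
            "AR": (31.8, 0.5, 31, 32), "PR": (14.1, 0.6, 13, 15),
            "CR": (15.0, 0.0, 15, 15), "UR": (5.0, 0.0, 5, 5),
            "LR": (24.3, 0.7, 23, 25), "PV": (42.9, 0.4, 42, 43),
            "CV": (29.5, 0.5, 29, 30),
        },
        "measurements": {
            "BDD": (6.8, 0.9, 5.8, 7.9), "BDA": (7.5, 0.5, 6.6, 8.2),
            "BWD": (6.5, 0.8, 5.6, 8.2), "HL": (19.4, 0.7, 18.3, 20.2),
            "SNL": (6.1, 0.1, 6.0, 6.3), "OD": (2.3, 0.2, 1.9, 2.5),
            "IW": (3.2, 0.3, 2.8, 3.6), "UJL": (5.3, 0.4, 4.7, 6.0),
            "CPD": (2.7, 0.1, 2.5, 2.9), "CPL": (4.8, 0.7, 4.4, 6.4),
            "PPL": (18.4, 0.3, 17.9, 18.7), "PDL": (26.6, 0.5, 26.1, 27.6),
            "PAL": (62.8, 1.4, 60.2, 64.1), "PFL": (7.7, 0.4, 7.2, 8.2),
            "DFBL": (69.1, 0.7, 68.1, 69.8), "AFBL": (32.4, 1.2, 30.5, 33.8),
            "CFL": (8.9, 0.4, 8.5, 9.7), "DFH": (4.1, 0.4, 3.4, 4.6),
            "AFH": (3.9, 0.7, 2.5, 4.6),
        },
        "qualitative": {"MDAS": "yes", "BCOP": "yes", "PCP": "no",
                        "VTP": "yes", "DSSS": "no", "BSTC": "yes",
                        "SBCF": "yes", "SADF": "yes"},
    },
    "Hyperoplus lanceolatus": {
        "SL_mm": (219.3, 32.7, 165.0, 291.0),
        "meristics": {
            "DP": (182.6, 6.4, 169, 194), "DR": (55.9, 0.8, 54, 57),
            "AR": (29.1, 0.8, 28, 30), "PR": (13.5, 0.5, 13, 14),
            "CR": (15.0, 0.0, 15, 15), "UR": (5.0, 0.0, 5, 5),
            "LR": (20.7, 0.8, 20, 22), "PV": (40.3, 0.8, 38, 42),
            "CV": (26.5, 0.7, 25, 28),
        },
        "measurements": {
            "BDD": (7.0, 0.9, 5.6, 8.8), "BDA": (6.7, 0.6, 5.2, 8.0),
            "BWD": (5.4, 0.8, 4.3, 7.2), "HL": (21.7, 0.6, 20.2, 23.0),
            "SNL": (7.2, 0.5, 5.0, 8.1), "OD": (2.5, 0.5, 2.0, 4.5),
            "IW": (3.3, 0.3, 2.7, 3.7), "UJL": (7.1, 0.3, 6.5, 8.1),
            "CPD": (2.5, 0.1, 2.3, 2.8), "CPL": (4.9, 0.4, 3.9, 5.7),
            "PPL": (20.8, 0.7, 19.5, 22.1), "PDL": (27.9, 1.0, 25.7, 30.4),
            "PAL": (64.9, 4.1, 45.4, 70.6), "PFL": (7.7, 0.6, 6.7, 8.7),
            "DFBL": (67.4, 1.1, 65.5, 69.2), "AFBL": (29.8, 1.0, 28.4, 32.1),
            "CFL": (8.9, 0.7, 7.6, 10.3), "DFH": (3.9, 0.6, 2.7, 5.7),
            "AFH": (4.1, 0.6, 2.7, 5.6),
        },
        "qualitative": {"MDAS": "yes", "BCOP": "yes", "PCP": "no",
                        "VTP": "yes", "DSSS": "yes", "BSTC": "unknown",
                        "SBCF": "yes", "SADF": "yes"},
    },
}


def standardize_percent_sl(raw_mm: float, sl_mm: float) -> float:
    """A measurement as percent of standard length: raw * 100 / SL."""
    if not (raw_mm > 0 and sl_mm > 0):
        raise ValueError("measurement and SL must both be positive")
    return raw_mm * 100.0 / sl_mm


@dataclass
class MorphTable:
    """Per-specimen morphology table.

    Required columns: specimen_id, species, SL_mm. Meristic columns hold
    raw counts, measurement columns raw mm, qualitative columns
    yes/no/unknown. Missing values are allowed (NaN / empty).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"specimen_id", "species", "SL_mm"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"morphology table missing columns {missing}")
        if self.df["specimen_id"].duplicated().any():
            dupes = self.df.loc[
                self.df["specimen_id"].duplicated(), "specimen_id"
            ].tolist()
            raise ValueError(f"duplicate specimen_id(s): {dupes}")
        sl = pd.to_numeric(self.df["SL_mm"], errors="coerce")
        if (sl <= 0).any():
            raise ValueError("SL_mm must be positive for all specimens")
        for total, (a, b) in COMPOSITE_MERISTICS.items():
            if {total, a, b} <= set(self.df.columns):
                sub = self.df[[total, a, b]].dropna()
                bad = sub[sub[total] != sub[a] + sub[b]]
                if len(bad):
                    raise ValueError(
                        f"{total} != {a} + {b} for rows {bad.index.tolist()}"
                    )
        self.df = self.df.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "MorphTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def species(self) -> list[str]:
        return sorted(self.df["species"].unique())

    def measurements_pct(self) -> pd.DataFrame:
        """Measurement columns converted from mm to %SL."""
        cols = [c for c in MEASUREMENT_COLS if c in self.df.columns]
        out = self.df[cols].apply(pd.to_numeric, errors="coerce")
        sl = pd.to_numeric(self.df["SL_mm"], errors="coerce")
        return out.mul(100.0).div(sl, axis=0)


def _fmt_summary(lo, hi, mean, sd, n) -> str:
    rng = f"{lo:g}" if lo == hi else f"{lo:g}–{hi:g}"
    if n == 1:
        return f"{mean:g} (1)"
    if lo == hi:
        return f"{mean:g} ± {sd:g} ({n})"
    return f"{rng}; {mean:g} ± {sd:g} ({n})"


def summarize_characters(t: MorphTable) -> pd.DataFrame:
    """Per species x character summary: range, mean, sample SD, n.

    Measurements are summarised in %SL, SL in mm, meristics as counts;
    qualitative characters report their observed states. Missing values
    are excluded per character. The ``formatted`` column renders
    "min-max; mean +/- SD (n)".
    """
    rows = []
    pct = t.measurements_pct()
    for sp, grp in t.df.groupby("species", sort=True):
        idx = grp.index
        numeric_blocks = [
            ("SL_mm", pd.DataFrame({"SL_mm": pd.to_numeric(
                grp["SL_mm"], errors="coerce")}), "mm"),
            ("meristic", grp[[c for c in MERISTIC_COLS
                              if c in grp.columns]].apply(
                pd.to_numeric, errors="coerce"), "count"),
            ("measurement", pct.loc[idx], "%SL"),
        ]
        for kind, block, unit in numeric_blocks:
            for col in block.columns:
                vals = block[col].dropna()
                if vals.empty:
                    continue
                n = len(vals)
                mean = float(vals.mean())
                sd = float(vals.std(ddof=1)) if n > 1 else np.nan
                rows.append({
                    "species": sp, "character": col,
                    "kind": "SL" if col == "SL_mm" else kind, "unit": unit,
                    "n": n, "min": float(vals.min()), "max": float(vals.max()),
                    "mean": round(mean, 4),
                    "sd": round(sd, 4) if n > 1 else np.nan,
                    "formatted": _fmt_summary(
                        round(float(vals.min()), 4), round(float(vals.max()), 4),
                        round(mean, 4), round(sd, 4) if n > 1 else 0.0, n),
                })
        for col in QUALITATIVE_COLS:
            if col not in grp.columns:
                continue
            vals = grp[col].dropna()
            vals = vals[vals != ""]
            if vals.empty:
                continue
            tally = vals.value_counts().to_dict()
            rows.append({
                "species": sp, "character": col, "kind": "qualitative",
                "unit": "", "n": int(len(vals)), "min": np.nan, "max": np.nan,
                "mean": np.nan, "sd": np.nan,
                "formatted": "; ".join(
                    f"{k} ({v})" for k, v in sorted(tally.items())),
            })
    return pd.DataFrame(rows)


def _dfa_design(t: MorphTable, variables: list[str]):
    """Complete-case design matrix: measurements in %SL, meristics raw."""
    pct = t.measurements_pct()
    blocks = {}
    for v in variables:
        if v in MEASUREMENT_COLS:
            blocks[v] = pct[v]
        else:
            blocks[v] = pd.to_numeric(t.df[v], errors="coerce")
    X = pd.DataFrame(blocks)
    keep = X.notna().all(axis=1)
    return (
        X.loc[keep].to_numpy(float),
        t.df.loc[keep, "species"].to_numpy(),
        t.df.loc[keep, "specimen_id"].tolist(),
        int((~keep).sum()),
    )


def select_dfa_variables(t: MorphTable, mode: str) -> list[str]:
    """Variables entering the DFA for the requested mode.

    ``meristic``: count characters minus composites (GR, TV) and any
    zero-variance column (e.g. the invariant principal caudal-fin ray
    count). ``morphometric``: the %SL measurements minus zero-variance
    columns. Qualitative characters never enter.
    """
    if mode == "meristic":
        candidates = [c for c in MERISTIC_COLS
                      if c in t.df.columns and c not in COMPOSITE_MERISTICS]
        values = t.df[candidates].apply(pd.to_numeric, errors="coerce")
    elif mode == "morphometric":
        candidates = [c for c in MEASUREMENT_COLS if c in t.df.columns]
        values = t.measurements_pct()[candidates]
    else:
        raise ValueError("mode must be 'meristic' or 'morphometric'")
    selected = [c for c in candidates
                if values[c].dropna().nunique() > 1]
    if not selected:
        raise ValueError(
            "no variables with variation remain; within-group scatter "
            "would be singular"
        )
    X, y, _, _ = _dfa_design(t, selected)
    counts = pd.Series(y).value_counts()
    if (counts >= 2).sum() < 2:
        raise ValueError(
            "DFA needs >= 2 groups with >= 2 complete specimens"
        )
    return selected


@dataclass
class DFAResult:
    """Canonical discriminant analysis output."""

    variables: list[str]
    groups: list[str]
    eigenvalues: np.ndarray
    raw_coefficients: np.ndarray  # variable x function
    std_coefficients: np.ndarray  # variable x function
    explained_pct: np.ndarray
    wilks_lambda: float
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    boxm_stat: float
    boxm_chi2: float
    boxm_df: int
    boxm_p: float
    scores: pd.DataFrame  # index specimen_id, columns DF1..DFm
    centroids: pd.DataFrame  # index group
    classification: pd.Series  # specimen_id -> predicted group
    n_dropped: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def n_functions(self) -> int:
        return len(self.eigenvalues)

    def group_ellipses(self, confidence: float = 0.95) -> dict:
        """Per-group (center, covariance, squared radius) of the first two
        discriminant scores, for confidence ellipses in score plots."""
        r2 = float(stats.chi2.ppf(confidence, df=2))
        out = {}
        labels = np.asarray(self._group_labels)
        sc = self.scores.iloc[:, :2].to_numpy()
        for g in self.groups:
            pts = sc[labels == g]
            if len(pts) < 3:
                continue
            out[g] = {
                "center": pts.mean(axis=0),
                "cov": np.cov(pts.T),
                "radius2": r2,
            }
        return out


def _box_m(X: np.ndarray, y: np.ndarray, groups: list[str]):
    """Box's M with its chi-square approximation; excludes n=1 groups."""
    p = X.shape[1]
    used = [g for g in groups if (y == g).sum() >= 2]
    warns = []
    if len(used) < len(groups):
        warns.append("groups with n=1 excluded from Box's M")
    if len(used) < 2:
        return np.nan, np.nan, 0, np.nan, warns + ["Box's M not computable"]
    ns = np.array([(y == g).sum() for g in used])
    covs = [np.cov(X[y == g].T, ddof=1).reshape(p, p) for g in used]
    N, g = int(ns.sum()), len(used)
    pooled = sum((n - 1) * S for n, S in zip(ns, covs)) / (N - g)
    sign_p, logdet_p = np.linalg.slogdet(pooled)
    logdets = [np.linalg.slogdet(S) for S in covs]
    if sign_p <= 0 or any(s <= 0 for s, _ in logdets):
        return np.nan, np.nan, 0, np.nan, warns + [
            "singular group covariance; Box's M undefined"]
    M = (N - g) * logdet_p - sum(
        (n - 1) * ld for n, (_, ld) in zip(ns, logdets))
    c1 = ((2 * p ** 2 + 3 * p - 1) / (6.0 * (p + 1) * (g - 1))) * (
        np.sum(1.0 / (ns - 1)) - 1.0 / (N - g))
    chi2 = M * (1.0 - c1)
    df = p * (p + 1) * (g - 1) // 2
    return float(M), float(chi2), int(df), float(stats.chi2.sf(chi2, df)), warns


def discriminant_analysis(t: MorphTable, variables: list[str]) -> DFAResult:
    """Multi-group canonical discriminant analysis.

    Complete-case deletion on the selected variables; eigenvalues and
    discriminant functions from the generalized symmetric eigenproblem
    ``B v = lambda W v``; standardized coefficients scale raw coefficients
    by the pooled within-group standard deviation of each variable; per
    function the variable with the largest |standardized coefficient| is
    given a positive sign. Classification is by nearest group centroid in
    discriminant space with equal priors.
    """
    X, y, ids, n_dropped = _dfa_design(t, variables)
    groups = sorted(pd.unique(y))
    g, p, N = len(groups), X.shape[1], X.shape[0]
    if g < 2:
        raise ValueError("DFA needs at least 2 groups")

    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for grp in groups:
        Xg = X[y == grp]
        mg = Xg.mean(axis=0)
        C = Xg - mg
        W += C.T @ C
        d = (mg - grand)[:, None]
        B += len(Xg) * (d @ d.T)

    try:
        evals, evecs = linalg.eigh(B, W)
    except linalg.LinAlgError as exc:
        raise ValueError(
            "singular within-group scatter; reduce or deselect variables "
            "(zero-variance or linearly dependent characters)"
        ) from exc
    order = np.argsort(evals)[::-1]
    m = min(g - 1, p)
    lam = np.clip(evals[order[:m]], 0.0, None)
    V = evecs[:, order[:m]]

    within_sd = np.sqrt(np.diag(W) / (N - g))
    std = V * within_sd[:, None]
    # sign convention: dominant loading positive per function
    for k in range(m):
        j = int(np.argmax(np.abs(std[:, k])))
        if std[j, k] < 0:
            std[:, k] *= -1
            V[:, k] *= -1

    total = lam.sum()
    explained = (100.0 * lam / total) if total > 0 else np.zeros(m)
    wilks = float(np.prod(1.0 / (1.0 + lam)))
    bart_chi2 = -(N - 1 - (p + g) / 2.0) * np.log(wilks)
    bart_df = p * (g - 1)
    bart_p = float(stats.chi2.sf(bart_chi2, bart_df))
    boxm, boxm_chi2, boxm_df, boxm_p, warns = _box_m(X, y, groups)

    func_names = [f"DF{k + 1}" for k in range(m)]
    scores = pd.DataFrame((X - grand) @ V, index=ids, columns=func_names)
    centroids = pd.DataFrame(
        [scores.to_numpy()[y == grp].mean(axis=0) for grp in groups],
        index=groups, columns=func_names)
    dists = np.stack([
        np.linalg.norm(scores.to_numpy() - centroids.loc[grp].to_numpy(),
                       axis=1)
        for grp in groups])
    classification = pd.Series(
        [groups[i] for i in dists.argmin(axis=0)], index=ids)

    result = DFAResult(
        variables=list(variables), groups=groups, eigenvalues=lam,
        raw_coefficients=V, std_coefficients=std, explained_pct=explained,
        wilks_lambda=wilks, bartlett_chi2=float(bart_chi2),
        bartlett_df=int(bart_df), bartlett_p=bart_p,
        boxm_stat=boxm, boxm_chi2=boxm_chi2, boxm_df=boxm_df, boxm_p=boxm_p,
        scores=scores, centroids=centroids, classification=classification,
        n_dropped=n_dropped, warnings=warns)
    result._group_labels = y  # retained for score-plot ellipses
    return result


def loo_classification_rate(t: MorphTable, variables: list[str]) -> float:
    """Leave-one-out reclassification rate of the nearest-centroid rule.

    A variable whose variance collapses to zero within a fold (the held-out
    specimen was its only source of variation) is dropped for that fold so
    the within-group scatter stays invertible.
    """
    X, y, ids, _ = _dfa_design(t, variables)
    df = t.df.set_index("specimen_id")
    correct = 0
    for sid in ids:
        rest = MorphTable(t.df[t.df["specimen_id"] != sid])
        Xr, _, _, _ = _dfa_design(rest, variables)
        fold_vars = [v for v, col in zip(variables, Xr.T)
                     if np.ptp(col) > 0]
        res = discriminant_analysis(rest, fold_vars)
        row = df.loc[sid]
        x = np.array([
            standardize_percent_sl(float(row[v]), float(row["SL_mm"]))
            if v in MEASUREMENT_COLS else float(row[v])
            for v in fold_vars])
        grand = _dfa_design(rest, fold_vars)[0].mean(axis=0)
        score = (x - grand) @ res.raw_coefficients
        d = np.linalg.norm(res.centroids.to_numpy() - score, axis=1)
        if res.groups[int(d.argmin())] == df.loc[sid, "species"]:
            correct += 1
    return correct / len(ids)


# --- rule-based identification key ------------------------------------------

GENUS_KEY_CHARS = ("PCP", "VTP", "DP", "PFL")
SPECIES_KEY_CHARS = {
    "Hyperoplus": ("DSSS", "LR", "GR", "CV", "TV", "DR", "AR"),
    "Ammodytes": ("BSTC", "SBCF", "SADF", "DP", "DR", "PV", "TV"),
}


def default_key_config() -> dict:
    """Key configuration derived from the published reference characters.

    Genus level uses premaxilla protrusibility (PCP), vomerine teeth /
    prevomer hooks (VTP), dermal plicae count (DP) and pectoral-fin length
    in %SL (PFL); species level uses the discriminating qualitative states
    and count ranges within each genus. Qualitative states recorded as
    "unknown" are not used against that species.
    """
    cfg: dict[str, dict] = {}
    for sp, ref in REFERENCE_CHARACTERS.items():
        genus = sp.split()[0]
        chars: dict[str, object] = {}
        for ch in GENUS_KEY_CHARS + SPECIES_KEY_CHARS[genus]:
            if ch in ref["qualitative"]:
                state = ref["qualitative"][ch]
                if state != "unknown":
                    chars[ch] = state
            elif ch in ref["meristics"]:
                _, _, lo, hi = ref["meristics"][ch]
                chars[ch] = (float(lo), float(hi))
            elif ch in ref["measurements"]:
                _, _, lo, hi = ref["measurements"][ch]
                chars[ch] = (float(lo), float(hi))
        # derived composite ranges from parts
        for total, (a, b) in COMPOSITE_MERISTICS.items():
            if total in SPECIES_KEY_CHARS[genus]:
                lo = ref["meristics"][a][2] + ref["meristics"][b][2]
                hi = ref["meristics"][a][3] + ref["meristics"][b][3]
                chars[total] = (float(lo), float(hi))
        cfg[sp] = {"genus": genus, "characters": chars}
    return cfg


@dataclass
class IdentificationResult:
    genus: str | None
    species: str | None
    evidence: list[dict]
    n_matched: int
    n_evaluated: int
    status: str  # "identified" | "genus-only" | "indeterminate"

    @property
    def confidence(self) -> float:
        return self.n_matched / self.n_evaluated if self.n_evaluated else 0.0


def _char_value(row, char: str):
    """Character value from a specimen row; measurements converted to %SL."""
    val = row.get(char)
    if val is None or (isinstance(val, float) and np.isnan(val)):
        return None
    if char in QUALITATIVE_COLS:
        s = str(val).strip().lower()
        return s if s in ("yes", "no") else None
    val = float(val)
    if char in MEASUREMENT_COLS:
        sl = row.get("SL_mm")
        if sl is None or (isinstance(sl, float) and np.isnan(sl)):
            return None
        return standardize_percent_sl(val, float(sl))
    return val


def _score(row, chars: dict) -> tuple[int, int, list[dict]]:
    matched = evaluated = 0
    evidence = []
    for ch, expect in chars.items():
        val = _char_value(row, ch)
        if val is None:
            continue
        evaluated += 1
        if isinstance(expect, tuple):
            ok = expect[0] <= val <= expect[1]
            exp_txt = f"{expect[0]:g}–{expect[1]:g}"
        else:
            ok = val == expect
            exp_txt = expect
        matched += ok
        evidence.append({"character": ch, "value": val,
                         "expected": exp_txt, "match": ok})
    return matched, evaluated, evidence


def identification_key(row, key_config: dict | None = None
                       ) -> IdentificationResult:
    """Identify a specimen from a morphology-table row.

    The row is a mapping (e.g. a :class:`MorphTable` row as a dict or
    pandas Series) of character abbreviations to values, with measurements
    in mm alongside SL_mm. Genus is decided first, then species within the
    genus; an evidence tie or an absence of usable characters yields an
    indeterminate result listing the conflict.
    """
    if key_config is None:
        key_config = default_key_config()
    if hasattr(row, "to_dict"):
        row = row.to_dict()

    genera: dict[str, list[str]] = {}
    for sp, entry in key_config.items():
        genera.setdefault(entry["genus"], []).append(sp)

    # genus stage: score the genus-level characters of any member species
    genus_scores = {}
    for genus, members in genera.items():
        chars = {ch: v for ch, v in key_config[members[0]]["characters"].items()
                 if ch in GENUS_KEY_CHARS}
        # DP ranges differ between congeners; use the genus-wide envelope
        for ch in list(chars):
            if isinstance(chars[ch], tuple):
                los, his = zip(*(
                    key_config[m]["characters"][ch] for m in members
                    if isinstance(key_config[m]["characters"].get(ch), tuple)))
                chars[ch] = (min(los), max(his))
        genus_scores[genus] = _score(row, chars)

    best = sorted(genus_scores.items(),
                  key=lambda kv: (-(kv[1][0] / kv[1][1]) if kv[1][1] else 0.0,
                                  kv[0]))
    evaluated_any = any(s[1] for s in genus_scores.values())
    if not evaluated_any:
        return IdentificationResult(None, None, [], 0, 0, "indeterminate")
    (g1, (m1, e1, ev1)), (g2, (m2, e2, _)) = best[0], best[1]
    f1 = m1 / e1 if e1 else 0.0
    f2 = m2 / e2 if e2 else 0.0
    if e1 == 0 or f1 <= f2:
        ev = ev1 + [{"character": "genus", "value": "tie",
                     "expected": f"{g1} vs {g2}", "match": False}]
        return IdentificationResult(None, None, ev, m1, e1, "indeterminate")
    genus = g1

    # species stage within the chosen genus
    sp_scores = {}
    for sp in genera[genus]:
        chars = {ch: v for ch, v in key_config[sp]["characters"].items()
                 if ch in SPECIES_KEY_CHARS[genus]}
        sp_scores[sp] = _score(row, chars)
    ranked = sorted(sp_scores.items(),
                    key=lambda kv: (-(kv[1][0] / kv[1][1]) if kv[1][1] else 0.0,
                                    kv[0]))
    (s1, (sm1, se1, sev1)) = ranked[0]
    if len(ranked) > 1:
        (s2, (sm2, se2, _)) = ranked[1]
        sf1 = sm1 / se1 if se1 else 0.0
        sf2 = sm2 / se2 if se2 else 0.0
        if se1 == 0 or sf1 <= sf2:
            ev = ev1 + sev1 + [{"character": "species", "value": "tie",
                               "expected": f"{s1} vs {s2}", "match": False}]
            return IdentificationResult(genus, None, ev, m1 + sm1,
                                        e1 + se1, "genus-only")
    return IdentificationResult(
        genus, s1, ev1 + sev1, m1 + sm1, e1 + se1, "identified")
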