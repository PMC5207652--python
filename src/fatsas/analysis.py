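"""Correlation, best-slice search, repeatability and group-difference
statistics over a cohort of quantified subjects.

The best-slice search exhaustively scans all size-k combinations of the
standardized half-level grid and maximizes the Pearson correlation between
the (summed) slice areas and the whole-region volume; the slices in a
combination need not be contiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .grid import BinaryMask, check_same_grid

log = logging.getLogger(__name__)

HIST_PARAMS = ("m", "md", "p", "lq", "uq")


class DegenerateInputError(ValueError):
    pass


def pcc(x, y, name_x: str = "x", name_y: str = "y") -> float:
    """Sample Pearson correlation coefficient (n-1 covariance convention,
    which cancels in the ratio)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("pcc needs two equal-length 1D samples of length >= 3")
    for arr, name in ((x, name_x), (y, name_y)):
        if np.ptp(arr) == 0:
            raise DegenerateInputError(
                f"correlation undefined: variable '{name}' is constant"
            )
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    return min(1.0, max(-1.0, r))


def scc(x, y, name_x: str = "x", name_y: str = "y") -> float:
    """Spearman rank correlation: PCC of average-ranked data."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return pcc(
        stats.rankdata(x, method="average"),
        stats.rankdata(y, method="average"),
        name_x=name_x,
        name_y=name_y,
    )


@dataclass(frozen=True)
class BestSliceResult:
    k: int
    labels: tuple[str, ...]
    rho: float

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("best-slice labels must be distinct")
        if abs(self.rho) > 1 + 1e-12:
            raise ValueError("|rho| must be <= 1")


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    p_t: float
    p_mwu: float


@dataclass
class CohortTable:
    """Per-subject normalized measurements feeding all cohort statistics.

    ``data`` holds one row per subject with scalar variables (normalized
    chest volumes ``SV_C``/``VV_C``, optional single-slice areas ``SA_A``,
    ``VA_A``, ``SA_T``, ``VA_T``, optional ``BMI`` and ``group``, and
    optional volume-scope histogram parameters ``SVH_C_<p>`` /
    ``VVH_C_<p>``).  ``sat_areas``/``vat_areas`` hold normalized chest
    slice areas per standardized grid label (subjects x labels).
    Slice-scope histogram parameters per label are optional.
    """

    data: pd.DataFrame
    grid_labels: list[str]
    sat_areas: pd.DataFrame
    vat_areas: pd.DataFrame
    sat_slice_hist: dict[str, pd.DataFrame] = field(default_factory=dict)
    vat_slice_hist: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, areas in (("sat_areas", self.sat_areas), ("vat_areas", self.vat_areas)):
            if list(areas.columns) != list(self.grid_labels):
                raise ValueError(f"{name} columns must equal grid_labels")
            if not areas.index.equals(self.data.index):
                raise ValueError(f"{name} subjects must match data subjects")
            if areas.isna().any().any():
                raise ValueError(f"{name} must have a value for every grid label")

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def areas(self, compartment: str) -> pd.DataFrame:
        return {"SAT": self.sat_areas, "VAT": self.vat_areas}[compartment]

    def volume(self, compartment: str) -> pd.Series:
        return self.data[{"SAT": "SV_C", "VAT": "VV_C"}[compartment]]

    def slice_hist(self, compartment: str) -> dict[str, pd.DataFrame]:
        return {"SAT": self.sat_slice_hist, "VAT": self.vat_slice_hist}[compartment]


def best_slices(cohort: CohortTable, compartment: str, k: int) -> BestSliceResult:
    """Exhaustive search for the k standardized levels whose summed slice
    area correlates maximally (PCC) with the whole-region volume.

    Ties resolve to the most cranial (lexicographically smallest by grid
    order) label combination.
    """
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2, or 3")
    if cohort.n_subjects < 4:
        raise ValueError("best-slice search needs at least 4 subjects")
    areas = cohort.areas(compartment)
    vol = cohort.volume(compartment).to_numpy()
    if np.ptp(vol) == 0:
        raise DegenerateInputError(f"{compartment} volumes are constant")
    a = areas.to_numpy()
    best_rho, best_combo = -np.inf, None
    for combo in combinations(range(len(cohort.grid_labels)), k):
        s = a[:, combo].sum(axis=1)
        if np.ptp(s) == 0:
            continue
        rho = pcc(s, vol)
        if rho > best_rho + 1e-15:
            best_rho, best_combo = rho, combo
    if best_combo is None:
        raise DegenerateInputError(
            f"{compartment} slice areas are constant at every grid label"
        )
    labels = tuple(cohort.grid_labels[i] for i in best_combo)
    return BestSliceResult(k=k, labels=labels, rho=best_rho)


def jaccard_precision(s1, s2) -> float:
    """|S1 n S2| / |S1 u S2| between two binary segmentations."""
    if isinstance(s1, BinaryMask) and isinstance(s2, BinaryMask):
        check_same_grid(s1, s2)
        a, b = s1.values, s2.values
    else:
        a = np.asarray(s1, dtype=bool)
        b = np.asarray(s2, dtype=bool)
        if a.shape != b.shape:
            raise ValueError("masks must share a grid")
    union = np.count_nonzero(a | b)
    if union == 0:
        raise DegenerateInputError("Jaccard undefined: both masks empty")
    return np.count_nonzero(a & b) / union


def group_compare(
    values_a, values_b, variable: str, welch: bool = False
) -> GroupComparison:
    """Two-sided unpaired t-test (pooled variance by default, Welch by
    option) and Mann-Whitney U with normal approximation and tie
    correction."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            log.warning("zero variance with equal means for %s; p = 1", variable)
            p_t = p_u = 1.0
        else:
            p_t = p_u = 0.0
    else:
        p_t = float(stats.ttest_ind(a, b, equal_var=not welch).pvalue)
        p_u = float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        )
    return GroupComparison(
        variable=variable,
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
        p_t=p_t, p_mwu=p_u,
    )


def _pair_row(cohort, name_a, name_b, x, y, with_scc) -> dict:
    row = {"pair": f"{name_a},{name_b}", "rho_pcc": np.nan, "rho_scc": np.nan,
           "missing": False}
    if x is None or y is None:
        row["missing"] = True
        return row
    try:
        row["rho_pcc"] = pcc(x, y, name_a, name_b)
        if with_scc:
            row["rho_scc"] = scc(x, y, name_a, name_b)
    except DegenerateInputError as e:
        log.warning("correlation row %s: %s", row["pair"], e)
        row["missing"] = True
    return row


def correlation_report(cohort: CohortTable, with_scc: bool = True) -> pd.DataFrame:
    """The full correlation table: volume-to-area (with best 1/2/3 chest
    slices), area-to-area, volume-histogram-to-best-slice-histogram, and
    BMI pairings.  Missing variables yield flagged rows, not errors.

    No multiple-testing correction is applied; coefficients are raw.
    """
    df = cohort.data

    def col(name):
        return df[name].to_numpy() if name in df.columns else None

    best = {c: best_slices(cohort, c, 1) for c in ("SAT", "VAT")}
    best_label = {c: best[c].labels[0] for c in ("SAT", "VAT")}
    best_area = {
        c: cohort.areas(c)[best_label[c]].to_numpy() for c in ("SAT", "VAT")
    }

    rows: list[dict] = []
    # volume-to-area
    for comp, v_name, prefix in (("SAT", "SV_C", "SA"), ("VAT", "VV_C", "VA")):
        v = col(v_name)
        rows.append(_pair_row(cohort, v_name, f"{prefix}_A", v, col(f"{prefix}_A"), with_scc))
        rows.append(_pair_row(cohort, v_name, f"{prefix}_T", v, col(f"{prefix}_T"), with_scc))
        for k in (1, 2, 3):
            r = best[comp] if k == 1 else best_slices(cohort, comp, k)
            rows.append({
                "pair": f"{v_name},{prefix}_C ({k} sl)",
                "rho_pcc": r.rho,
                "rho_scc": np.nan,
                "missing": False,
                "labels": "+".join(r.labels),
            })
    # area-to-area (chest area at the best single slice)
    for comp, prefix in (("SAT", "SA"), ("VAT", "VA")):
        for other in ("A", "T"):
            rows.append(_pair_row(
                cohort, f"{prefix}_C", f"{prefix}_{other}",
                best_area[comp], col(f"{prefix}_{other}"), with_scc,
            ))
    # histogram volume-to-slice at the best slice
    for comp, vol_pre, sl_pre in (("SAT", "SVH_C", "SAH_C"), ("VAT", "VVH_C", "VAH_C")):
        sl_hist = cohort.slice_hist(comp)
        for p in HIST_PARAMS:
            x = col(f"{vol_pre}_{p}")
            y = (
                sl_hist[p][best_label[comp]].to_numpy()
                if p in sl_hist and best_label[comp] in sl_hist[p].columns
                else None
            )
            rows.append(_pair_row(cohort, f"{vol_pre}_{p}", f"{sl_pre}_{p}", x, y, with_scc))
    # BMI pairings
    bmi = col("BMI")
    for name in ("SV_C", "VV_C", "SA_A", "SA_T", "VA_A", "VA_T"):
        rows.append(_pair_row(cohort, "BMI", name, bmi, col(name), with_scc))
    rows.append(_pair_row(cohort, "BMI", "SA_C", bmi, best_area["SAT"], with_scc))
    rows.append(_pair_row(cohort, "BMI", "VA_C", bmi, best_area["VAT"], with_scc))
    return pd.DataFrame(rows)
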