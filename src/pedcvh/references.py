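"""Growth and blood-pressure reference standards.

Pediatric classification of BMI and blood pressure is relative: a child's
measurement is compared against sex- and age-specific (and, for BP,
height-specific) percentiles from national reference tables.  This module
holds those tables and the LMS (lambda-mu-sigma) machinery used to move
between measurements, z-scores and percentiles.

The reference publications themselves are external; the package ships
synthetic-but-realistic fixture tables (see :mod:`pedcvh.tables`) in a
documented TSV layout and accepts user-supplied tables in the same layout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LMSReference",
    "BPReference",
    "ReferenceSet",
    "ReferenceValidationError",
    "lms_zscore",
    "lms_value",
    "load_lms",
    "load_bp",
    "load_reference_set",
    "default_reference_set",
    "band_labels",
    "assign_height_band",
    "bmi_cutoffs",
    "bp_cutoffs",
    "DEFAULT_BAND_EDGES",
]

SEXES = ("male", "female")

#: Height-percentile band edges (percent); bands are half-open, closed on
#: the left, so a child exactly at an edge falls in the upper band.
DEFAULT_BAND_EDGES = (5.0, 25.0, 50.0, 75.0, 95.0)


class ReferenceValidationError(ValueError):
    """A reference table failed a structural or invariant check."""


def band_labels(edges=DEFAULT_BAND_EDGES) -> list[str]:
    """Labels for the height bands implied by percentile ``edges``."""
    edges = [float(e) for e in edges]
    labels = [f"<P{edges[0]:g}"]
    labels += [f"P{a:g}-P{b:g}" for a, b in zip(edges[:-1], edges[1:])]
    labels.append(f">=P{edges[-1]:g}")
    return labels


def lms_zscore(x, L, M, S):
    """z-score of measurement ``x`` under LMS parameters.

    z = ((x/M)^L - 1) / (L*S) for L != 0, and ln(x/M)/S for L == 0.
    Accepts scalars or aligned arrays; ``x`` must be positive.
    """
    x = np.asarray(x, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(x <= 0):
        raise ValueError("LMS z-score requires a positive measurement")
    ratio = x / M
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(
            L == 0,
            np.log(ratio) / S,
            (np.power(ratio, L) - 1.0) / (L * S),
        )
    return z if z.ndim else float(z)

def lms_value(z, L, M, S):
    """Inverse of :func:`lms_zscore`: the measurement at z-score ``z``."""
    z = np.asarray(z, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    with np.errstate(invalid="ignore"):
        x = np.where(
            L == 0,
            M * np.exp(S * z),
            M * np.power(1.0 + L * S * z, 1.0 / np.where(L == 0, 1.0, L)),
        )
    return x if x.ndim else float(x)


@dataclass(frozen=True)
class LMSReference:
    """Sex-specific LMS table on a common age grid.

    ``table`` has columns ``sex, age_years, L, M, S`` with a strictly
    increasing age grid per sex, M > 0 and S > 0 everywhere, and both
    sexes present.  L, M, S are linearly interpolated in age between grid
    points; ages outside the grid are a hard error (no extrapolation).
    """

    table: pd.DataFrame
    label: str = "lms"

    def __post_init__(self):
        t = self.table
        required = {"sex", "age_years", "L", "M", "S"}
        missing = required - set(t.columns)
        if missing:
            raise ReferenceValidationError(
                f"{self.label}: missing column(s) {sorted(missing)}"
            )
        bad_sex = set(t["sex"]) - set(SEXES)
        if bad_sex:
            raise ReferenceValidationError(f"{self.label}: unknown sex value(s) {bad_sex}")
        for sex in SEXES:
            sub = t[t["sex"] == sex]
            if sub.empty:
                raise ReferenceValidationError(f"{self.label}: no rows for sex={sex}")
            ages = sub["age_years"].to_numpy(dtype=float)
            if not np.all(np.diff(ages) > 0):
                raise ReferenceValidationError(
                    f"{self.label}: age grid not strictly increasing for sex={sex}"
                )
            for col in ("M", "S"):
                vals = sub[col].to_numpy(dtype=float)
                if not np.all(vals > 0):
                    row = sub.index[vals <= 0][0]
                    raise ReferenceValidationError(
                        f"{self.label}: {col} <= 0 at row {row} (sex={sex})"
                    )

    def age_range(self, sex: str) -> tuple[float, float]:
        ages = self.table.loc[self.table["sex"] == sex, "age_years"]
        return float(ages.min()), float(ages.max())

    def params(self, sex, age):
        """Interpolated (L, M, S) at ``age`` (scalar or array) for ``sex``.

        ``sex`` may be a scalar applying to all ages, or an array aligned
        with ``age``.
        """
        age = np.asarray(age, dtype=float)
        scalar = age.ndim == 0
        age = np.atleast_1d(age)
        sex_arr = np.broadcast_to(np.asarray(sex, dtype=object), age.shape)
        L = np.empty_like(age)
        M = np.empty_like(age)
        S = np.empty_like(age)
        for s in SEXES:
            mask = sex_arr == s
            if not mask.any():
                continue
            sub = self.table[self.table["sex"] == s]
            grid = sub["age_years"].to_numpy(dtype=float)
            a = age[mask]
            if np.any(a < grid[0]) or np.any(a > grid[-1]):
                lo, hi = grid[0], grid[-1]
                raise ValueError(
                    f"{self.label}: age outside reference coverage "
                    f"[{lo:g}, {hi:g}] for sex={s} (no extrapolation)"
                )
            L[mask] = np.interp(a, grid, sub["L"].to_numpy(dtype=float))
            M[mask] = np.interp(a, grid, sub["M"].to_numpy(dtype=float))
            S[mask] = np.interp(a, grid, sub["S"].to_numpy(dtype=float))
        if scalar:
            return float(L[0]), float(M[0]), float(S[0])
        return L, M, S

    def zscore(self, sex, age, value):
        L, M, S = self.params(sex, age)
        return lms_zscore(value, L, M, S)

    def percentile_of(self, sex, age, value):
        """Percentile (0–100) of ``value`` for a child of given sex/age."""
        z = self.zscore(sex, age, value)
        return 100.0 * stats.norm.cdf(z)

    def value_at_percentile(self, sex, age, p):
        """Measurement at percentile ``p`` (0 < p < 100)."""
        p = np.asarray(p, dtype=float)
        if np.any((p <= 0) | (p >= 100)):
            raise ValueError("percentile must be strictly between 0 and 100")
        z = stats.norm.ppf(p / 100.0)
        L, M, S = self.params(sex, age)
        return lms_value(z, L, M, S)


@dataclass(frozen=True)
class BPReference:
    """Blood-pressure percentile grid indexed by sex, completed age in
    years, and height-percentile band.

    ``table`` columns: ``sex, age_years, height_band, sbp_p90, sbp_p95,
    dbp_p90, dbp_p95`` (mmHg).  The grid must be complete over
    sex x age x band and satisfy p95 >= p90 in every cell.
    """

    table: pd.DataFrame
    band_edges: tuple[float, ...] = DEFAULT_BAND_EDGES
    label: str = "bp"
    _index: pd.DataFrame = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        t = self.table
        required = {"sex", "age_years", "height_band",
                    "sbp_p90", "sbp_p95", "dbp_p90", "dbp_p95"}
        missing = required - set(t.columns)
        if missing:
            raise ReferenceValidationError(
                f"{self.label}: missing column(s) {sorted(missing)}"
            )
        labels = band_labels(self.band_edges)
        bad = set(t["height_band"]) - set(labels)
        if bad:
            raise ReferenceValidationError(
                f"{self.label}: unknown height band(s) {sorted(bad)}; expected {labels}"
            )
        ages = sorted(set(int(a) for a in t["age_years"]))
        cells = set(zip(t["sex"], t["age_years"].astype(int), t["height_band"]))
        expected = set(itertools.product(SEXES, ages, labels))
        holes = expected - cells
        if holes:
            example = sorted(holes)[0]
            raise ReferenceValidationError(
                f"{self.label}: incomplete grid — {len(holes)} missing cell(s), "
                f"e.g. {example}"
            )
        if len(cells) != len(t):
            raise ReferenceValidationError(f"{self.label}: duplicate grid cells")
        for pair in (("sbp_p90", "sbp_p95"), ("dbp_p90", "dbp_p95")):
            lo, hi = t[pair[0]].to_numpy(float), t[pair[1]].to_numpy(float)
            if not np.all(hi >= lo):
                row = t.index[hi < lo][0]
                raise ReferenceValidationError(
                    f"{self.label}: {pair[1]} < {pair[0]} at row {row}"
                )
        idx = t.set_index(["sex", t["age_years"].astype(int), "height_band"])
        idx.index.names = ["sex", "age_years", "height_band"]
        object.__setattr__(self, "_index", idx)

    @property
    def ages(self) -> list[int]:
        return sorted(set(int(a) for a in self.table["age_years"]))

    def cutoffs(self, sex, age_years: int, band: str):
        """(sbp_p90, sbp_p95, dbp_p90, dbp_p95) for one grid cell."""
        try:
            row = self._index.loc[(sex, int(age_years), band)]
        except KeyError:
            raise ValueError(
                f"{self.label}: no cell for sex={sex}, age={int(age_years)}, "
                f"band={band}"
            ) from None
        return tuple(float(row[c]) for c in ("sbp_p90", "sbp_p95", "dbp_p90", "dbp_p95"))


def assign_height_band(height_percentile, edges=DEFAULT_BAND_EDGES):
    """Map height percentile(s) to band label(s).

    Bands are half-open, closed on the left; a percentile exactly at an
    edge goes to the upper band.
    """
    labels = np.asarray(band_labels(edges), dtype=object)
    p = np.asarray(height_percentile, dtype=float)
    idx = np.searchsorted(np.asarray(edges, dtype=float), p, side="right")
    out = labels[idx]
    return out if p.ndim else str(out)


@dataclass(frozen=True)
class ReferenceSet:
    """Everything the scorer needs: BMI and height LMS tables plus the BP
    percentile grid, with a provenance label."""

    bmi: LMSReference
    height: LMSReference
    bp: BPReference
    provenance: str = "unspecified"

    def __post_init__(self):
        for ref, name in ((self.bmi, "bmi"), (self.height, "height")):
            for sex in SEXES:
                lo, hi = ref.age_range(sex)
                if lo > 6.0 or hi < 18.0:
                    raise ReferenceValidationError(
                        f"{name} reference does not span ages 6–18 for sex={sex} "
                        f"(covers [{lo:g}, {hi:g}])"
                    )


def load_lms(path, label=None) -> LMSReference:
    """Load an LMS TSV (columns sex, age_years, L, M, S)."""
    label = label or str(path)
    try:
        t = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - passthrough context
        raise ReferenceValidationError(f"{label}: cannot read TSV ({exc})") from exc
    return LMSReference(table=t, label=label)


def load_bp(path, band_edges=DEFAULT_BAND_EDGES, label=None) -> BPReference:
    """Load a BP grid TSV (columns sex, age_years, height_band, sbp_p90,
    sbp_p95, dbp_p90, dbp_p95)."""
    label = label or str(path)
    try:
        t = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover
        raise ReferenceValidationError(f"{label}: cannot read TSV ({exc})") from exc
    return BPReference(table=t, band_edges=tuple(band_edges), label=label)


def load_reference_set(bmi_path, bp_path, height_path,
                       band_edges=DEFAULT_BAND_EDGES,
                       provenance="user-supplied") -> ReferenceSet:
    """Load and validate a full reference set from three TSV files."""
    return ReferenceSet(
        bmi=load_lms(bmi_path, label=f"bmi:{bmi_path}"),
        height=load_lms(height_path, label=f"height:{height_path}"),
        bp=load_bp(bp_path, band_edges=band_edges, label=f"bp:{bp_path}"),
        provenance=provenance,
    )


def default_reference_set() -> ReferenceSet:
    """The synthetic reference tables shipped with the package."""
    pkg = resources.files("pedcvh") / "data"
    return load_reference_set(
        pkg / "bmi_lms.tsv", pkg / "bp_reference.tsv", pkg / "height_lms.tsv",
        provenance="pedcvh synthetic fixture tables",
    )


def bmi_cutoffs(refs: ReferenceSet, sex, age):
    """BMI 85th and 95th percentile cut-offs (kg/m^2) for sex/age."""
    p85 = refs.bmi.value_at_percentile(sex, age, 85.0)
    p95 = refs.bmi.value_at_percentile(sex, age, 95.0)
    return p85, p95


def bp_cutoffs(refs: ReferenceSet, sex, age, height):
    """(sbp_p90, sbp_p95, dbp_p90, dbp_p95) for a child of given sex,
    age (truncated to completed years) and height (cm).

    The height is converted to a height percentile via the height LMS
    reference, mapped to a band (ties to the upper band), and the BP grid
    cell for (sex, floor(age), band) is returned.
    """
    if height <= 0:
        raise ValueError("height must be positive")
    pct = refs.height.percentile_of(sex, age, height)
    band = assign_height_band(pct, refs.bp.band_edges)
    return refs.bp.cutoffs(sex, int(np.floor(age)), band)
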