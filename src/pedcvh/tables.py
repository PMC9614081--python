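"""Builders for the synthetic reference tables shipped with the package.

The national BMI/height/BP reference publications used for classifying
Chinese children are not redistributable data files, so the package ships
*synthetic* tables with the right structure and realistic magnitudes:
smooth LMS curves for BMI and height over ages 6–18, and a complete
sex x age x height-band blood-pressure percentile grid.  They exist so the
pipeline is runnable and testable end to end; they are not the published
national standards, and users with access to real tables can supply them
in the same TSV layout.

The shipped ``src/pedcvh/data/*.tsv`` files are the frozen output of
:func:`write_tables`; a test asserts they match, so accidental edits to
either side are caught.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .references import DEFAULT_BAND_EDGES, band_labels

AGE_GRID = np.arange(6.0, 18.0 + 0.25, 0.5)
BP_AGES = np.arange(6, 19)


def synthetic_bmi_lms() -> pd.DataFrame:
    """Smooth BMI-for-age LMS curves, both sexes, ages 6–18 by 0.5 y."""
    rows = []
    for sex in ("male", "female"):
        for age in AGE_GRID:
            t = age - 6.0
            if sex == "male":
                L = -1.60 + 0.020 * t
                M = 15.40 + 0.35 * t + 0.012 * t**2
                S = 0.1050 + 0.0015 * t
            else:
                L = -1.50 + 0.015 * t
                M = 15.20 + 0.40 * t + 0.008 * t**2
                S = 0.1000 + 0.0012 * t
            rows.append((sex, age, round(L, 4), round(M, 4), round(S, 4)))
    return pd.DataFrame(rows, columns=["sex", "age_years", "L", "M", "S"])


def synthetic_height_lms() -> pd.DataFrame:
    """Smooth height-for-age LMS curves (L=1: plain Gaussian in height)."""
    rows = []
    for sex in ("male", "female"):
        for age in AGE_GRID:
            t = age - 6.0
            if sex == "male":
                M = 116.0 + 5.6 * t - 0.05 * t**2
                S = 0.0430
            else:
                M = 115.5 + 5.4 * t - 0.10 * t**2
                S = 0.0400
            rows.append((sex, age, 1.0, round(M, 4), S))
    return pd.DataFrame(rows, columns=["sex", "age_years", "L", "M", "S"])


def synthetic_bp_reference(band_edges=DEFAULT_BAND_EDGES) -> pd.DataFrame:
    """Complete BP percentile grid: sex x completed age x height band.

    Percentiles rise linearly with age and with the height band, mirroring
    the structure of published pediatric BP standards.
    """
    labels = band_labels(band_edges)
    rows = []
    for sex in ("male", "female"):
        sex_off = 1.0 if sex == "male" else 0.0
        for age in BP_AGES:
            for b, lab in enumerate(labels):
                band_off = b - (len(labels) - 1) / 2.0
                sbp90 = 96.0 + 1.15 * age + 1.5 * band_off + sex_off
                dbp90 = 57.0 + 0.75 * age + 0.8 * band_off + 0.5 * sex_off
                rows.append((
                    sex, int(age), lab,
                    round(sbp90, 1), round(sbp90 + 4.0, 1),
                    round(dbp90, 1), round(dbp90 + 3.0, 1),
                ))
    return pd.DataFrame(rows, columns=[
        "sex", "age_years", "height_band",
        "sbp_p90", "sbp_p95", "dbp_p90", "dbp_p95",
    ])


def write_tables(outdir) -> dict[str, Path]:
    """Write the three synthetic reference TSVs into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in (
        ("bmi_lms", synthetic_bmi_lms()),
        ("height_lms", synthetic_height_lms()),
        ("bp_reference", synthetic_bp_reference()),
    ):
        p = outdir / f"{name}.tsv"
        frame.to_csv(p, sep="\t", index=False)
        paths[name] = p
    return paths


if __name__ == "__main__":  # pragma: no cover
    import sys

    write_tables(sys.argv[1] if len(sys.argv) > 1 else Path(__file__).parent / "data")
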