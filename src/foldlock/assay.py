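"""Fluorescence quantification: peak readout, I0/I ratios, Stern–Volmer
fits, LOD estimation and specificity classification.

The probe readout is the emission intensity with (*I*) and without (*I0*)
target; quenching follows the linear Stern–Volmer law

    I0/I = 1 + Ksv · c

with the target concentration ``c`` (M) as the quencher and Ksv (M⁻¹) the
fitted sensitivity slope.  The limit of detection is the smallest
concentration whose predicted quench ratio exceeds the blank by ``k`` times
the blank coefficient of variation (k = 3 by default).  Non-target
additions can *increase* the emission; such I0/I < 1 values are preserved
(negative log2 ratios), never clipped.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AssayError",
    "EmissionSpectrum",
    "TitrationSeries",
    "SternVolmerFit",
    "LODResult",
    "SpecificityResult",
    "peak_intensity",
    "quench_ratio",
    "stern_volmer_fit",
    "lod_estimate",
    "amount_moles",
    "specificity_matrix",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "load_titration_manifest",
    "load_panel_manifest",
]

DEFAULT_DETECTION_THRESHOLD = 2.0  # I0/I at or above => "detected"
MIN_SPECTRUM_POINTS = 8


class AssayError(ValueError):
    """Raised for malformed spectra, series or degenerate fits."""


@dataclass(frozen=True)
class EmissionSpectrum:
    """A wavelength–intensity trace from one emission scan."""

    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    excitation_nm: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "intensities", y)
        if w.ndim != 1 or y.ndim != 1 or w.size != y.size:
            raise AssayError("wavelengths and intensities must be equal-length 1-D")
        if w.size < MIN_SPECTRUM_POINTS:
            raise AssayError(
                f"spectrum needs >= {MIN_SPECTRUM_POINTS} points, got {w.size}"
            )
        if not np.all(np.diff(w) > 0):
            raise AssayError("wavelengths must be strictly increasing")
        if np.any(y < 0):
            raise AssayError("negative intensities; baseline-correct first")


@dataclass
class TitrationSeries:
    """Spectra (or peak intensities) across a target concentration series.

    Exactly one zero concentration defines I0.  Entries are stored sorted by
    concentration.
    """

    probe: str
    concentrations_m: np.ndarray
    spectra: list[EmissionSpectrum] | None = None
    intensities: np.ndarray | None = None
    readout_window_nm: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations_m, dtype=float)
        if c.size == 0:
            raise AssayError("empty concentration series")
        if np.any(c < 0):
            raise AssayError("concentrations must be non-negative")
        if np.count_nonzero(c == 0.0) != 1:
            raise AssayError(
                "series must contain the zero (I0) concentration exactly once"
            )
        if self.spectra is None and self.intensities is None:
            raise AssayError("series needs spectra or peak intensities")
        order = np.argsort(c, kind="stable")
        c = c[order]
        if self.spectra is not None:
            if len(self.spectra) != c.size:
                raise AssayError("one spectrum per concentration required")
            self.spectra = [self.spectra[i] for i in order]
        if self.intensities is not None:
            y = np.asarray(self.intensities, dtype=float)
            if y.size != c.size:
                raise AssayError("one intensity per concentration required")
            self.intensities = y[order]
        self.concentrations_m = c

    def peak_intensities(self) -> np.ndarray:
        """Per-concentration readout intensity (max in the readout window)."""
        if self.intensities is not None:
            return self.intensities
        window = self.readout_window_nm
        return np.array(
            [peak_intensity(s, window) for s in self.spectra]  # type: ignore[union-attr]
        )


def peak_intensity(
    spectrum: EmissionSpectrum,
    window_nm: tuple[float, float] | None = None,
    at_nm: float | None = None,
) -> float:
    """Readout intensity of a spectrum.

    Default is the maximum intensity inside ``window_nm`` (whole range when
    no window is given) — tolerant to small peak shifts; pass ``at_nm`` to
    read the intensity at the nearest tabulated wavelength instead.
    """
    w, y = spectrum.wavelengths_nm, spectrum.intensities
    if at_nm is not None:
        return float(y[np.argmin(np.abs(w - at_nm))])
    if window_nm is None:
        return float(y.max())
    lo, hi = window_nm
    mask = (w >= lo) & (w <= hi)
    if not mask.any():
        raise AssayError(
            f"readout window {window_nm} nm does not overlap the spectrum "
            f"range {w[0]:g}-{w[-1]:g} nm"
        )
    return float(y[mask].max())


def quench_ratio(series: TitrationSeries) -> list[tuple[float, float]]:
    """(concentration, I0/I) pairs; the zero point is 1 by definition."""
    c = series.concentrations_m
    y = series.peak_intensities()
    i0 = float(y[c == 0.0][0])
    if i0 <= 0:
        raise AssayError("non-positive I0 intensity")
    out: list[tuple[float, float]] = []
    for ci, yi in zip(c, y):
        if ci == 0.0:
            out.append((0.0, 1.0))
            continue
        if yi <= 0:
            raise AssayError(
                f"non-positive intensity {yi:g} at c={ci:g} M; cannot form I0/I"
            )
        out.append((float(ci), i0 / float(yi)))
    return out


@dataclass(frozen=True)
class SternVolmerFit:
    """Least-squares Stern–Volmer fit I0/I = intercept + Ksv·c."""

    ksv_per_m: float
    intercept: float
    intercept_fixed: bool
    r_squared: float
    residuals: np.ndarray
    n_points: int
    concentrations_m: np.ndarray
    ratios: np.ndarray

    def predict(self, conc_m: float | np.ndarray) -> np.ndarray:
        return self.intercept + self.ksv_per_m * np.asarray(conc_m, dtype=float)


def stern_volmer_fit(
    series: TitrationSeries | Sequence[tuple[float, float]],
    fix_intercept: bool = True,
) -> SternVolmerFit:
    """Fit the Stern–Volmer line to a titration.

    With ``fix_intercept`` (default) the model is I0/I = 1 + Ksv·c — the
    physically forced intercept, fitted by closed-form least squares through
    (0, 1); otherwise both intercept and slope are free.  Requires at least
    3 non-zero concentrations.
    """
    if isinstance(series, TitrationSeries):
        pairs = quench_ratio(series)
    else:
        pairs = [(float(c), float(r)) for c, r in series]
    c = np.array([p[0] for p in pairs])
    r = np.array([p[1] for p in pairs])
    if np.count_nonzero(c) < 3:
        raise AssayError("Stern-Volmer fit needs >= 3 non-zero concentrations")
    if np.allclose(c, c[0]):
        raise AssayError("degenerate series: all concentrations equal")
    if fix_intercept:
        # least squares of (r - 1) = Ksv * c
        ksv = float(np.dot(c, r - 1.0) / np.dot(c, c))
        intercept = 1.0
    else:
        coeffs = np.polyfit(c, r, 1)
        ksv, intercept = float(coeffs[0]), float(coeffs[1])
    pred = intercept + ksv * c
    resid = r - pred
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return SternVolmerFit(
        ksv_per_m=ksv,
        intercept=intercept,
        intercept_fixed=fix_intercept,
        r_squared=r2,
        residuals=resid,
        n_points=int(c.size),
        concentrations_m=c,
        ratios=r,
    )


@dataclass(frozen=True)
class LODResult:
    """Limit of detection under the k·CV-of-blank decision rule."""

    lod_m: float
    k: float
    cv_blank: float
    amount_mol: float | None
    volume_l: float | None


def amount_moles(conc_m: float, volume_l: float) -> float:
    """Absolute amount (mol) of target at ``conc_m`` in ``volume_l``."""
    return conc_m * volume_l


def lod_estimate(
    fit: SternVolmerFit,
    blank_replicates: Sequence[float],
    k: float = 3.0,
    volume_l: float | None = None,
) -> LODResult:
    """Smallest concentration with predicted I0/I >= 1 + k·CV(blank).

    For the linear model this is ``k·CV / Ksv``.  ``blank_replicates`` are
    repeated I0 intensity measurements (>= 3).  When ``volume_l`` is given,
    the corresponding absolute amount in moles is reported too.
    """
    blanks = np.asarray(blank_replicates, dtype=float)
    if blanks.size < 3:
        raise AssayError("need >= 3 blank replicates for the noise estimate")
    if np.any(blanks <= 0):
        raise AssayError("blank intensities must be positive")
    if fit.ksv_per_m <= 0:
        raise AssayError("Ksv <= 0: no quenching, LOD undefined")
    cv = float(blanks.std(ddof=1) / blanks.mean())
    lod = k * cv / fit.ksv_per_m
    amount = amount_moles(lod, volume_l) if volume_l is not None else None
    return LODResult(lod_m=lod, k=k, cv_blank=cv, amount_mol=amount,
                     volume_l=volume_l)


@dataclass
class SpecificityResult:
    """Per-miRNA quench ratios of one probe against a specificity panel."""

    probe: str
    table: pd.DataFrame  # columns: miRNA, I0, I, ratio, log2_ratio, detected
    threshold: float
    cognate: str | None = None

    def detected(self) -> list[str]:
        return list(self.table.loc[self.table["detected"], "miRNA"])


def specificity_matrix(
    probe: str,
    panel_measurements: Mapping[str, tuple[float, float]],
    threshold: float = DEFAULT_DETECTION_THRESHOLD,
    cognate: str | None = None,
) -> SpecificityResult:
    """Classify a panel of miRNAs by their quench ratio.

    ``panel_measurements`` maps miRNA id to ``(I0, I)`` intensities.  The
    detection call is ``I0/I >= threshold``; ratios below 1 (emission
    increase, as seen with non-target total RNA) yield negative log2 values
    and are kept as-is.
    """
    if not panel_measurements:
        raise AssayError("empty specificity panel")
    rows = []
    for mirna, (i0, i) in panel_measurements.items():
        if i0 <= 0:
            raise AssayError(f"missing or non-positive I0 for {mirna}")
        if i <= 0:
            raise AssayError(f"non-positive intensity for {mirna}")
        ratio = i0 / i
        rows.append(
            {
                "miRNA": mirna,
                "I0": float(i0),
                "I": float(i),
                "ratio": float(ratio),
                "log2_ratio": float(math.log2(ratio)),
                "detected": bool(ratio >= threshold),
            }
        )
    table = pd.DataFrame(rows)
    return SpecificityResult(probe=probe, table=table, threshold=threshold,
                             cognate=cognate)


# ---------------------------------------------------------------------------
# File I/O: spectra as two-column CSV, batches as JSON manifests
# ---------------------------------------------------------------------------


def read_spectrum_csv(path: str | Path, excitation_nm: float | None = None,
                      label: str = "") -> EmissionSpectrum:
    """Read a two-column spectrum CSV (header ``wavelength_nm,intensity``)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise AssayError(f"cannot parse {path}: {exc}") from exc
    cols = {c.lower(): c for c in df.columns}
    if "wavelength_nm" not in cols or "intensity" not in cols:
        raise AssayError(
            f"{path}: expected columns wavelength_nm,intensity; "
            f"found {list(df.columns)}"
        )
    bad = df[df[cols["intensity"]].isna() | df[cols["wavelength_nm"]].isna()]
    if len(bad):
        raise AssayError(
            f"{path}: non-numeric or missing values in rows "
            f"{[int(i) + 2 for i in bad.index[:5]]}"
        )
    return EmissionSpectrum(
        wavelengths_nm=df[cols["wavelength_nm"]].to_numpy(dtype=float),
        intensities=df[cols["intensity"]].to_numpy(dtype=float),
        excitation_nm=excitation_nm,
        label=label or path.stem,
    )


def write_spectrum_csv(spectrum: EmissionSpectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths_nm,
         "intensity": spectrum.intensities}
    ).to_csv(path, index=False)


def _manifest_dir(manifest_path: Path, payload: dict[str, Any]) -> Path:
    base = payload.get("base_dir")
    return (manifest_path.parent / base) if base else manifest_path.parent


def load_titration_manifest(path: str | Path) -> TitrationSeries:
    """Load a titration from a JSON manifest.

    Schema: ``{"probe": str, "excitation_nm": num?, "readout_window_nm":
    [lo, hi]?, "entries": [{"file": str, "concentration_m": num}, ...]}``;
    file paths are relative to the manifest.
    """
    path = Path(path)
    payload = json.loads(path.read_text())
    entries = payload.get("entries", [])
    if not entries:
        raise AssayError(f"{path}: manifest has no entries")
    base = _manifest_dir(path, payload)
    spectra, concs = [], []
    for e in entries:
        f = base / e["file"]
        if not f.exists():
            raise AssayError(f"{path}: spectrum file not found: {f}")
        spectra.append(
            read_spectrum_csv(f, excitation_nm=payload.get("excitation_nm"))
        )
        concs.append(float(e["concentration_m"]))
    window = payload.get("readout_window_nm")
    return TitrationSeries(
        probe=payload.get("probe", path.stem),
        concentrations_m=np.array(concs),
        spectra=spectra,
        readout_window_nm=tuple(window) if window else None,
    )


def load_panel_manifest(
    path: str | Path,
) -> tuple[str, dict[str, tuple[float, float]], str | None, tuple[float, float] | None]:
    """Load a specificity panel manifest.

    Schema: ``{"probe": str, "cognate": str?, "readout_window_nm": [lo,hi]?,
    "blank_file": str, "entries": [{"miRNA": str, "file": str}, ...]}``.
    Returns ``(probe, {miRNA: (I0, I)}, cognate, window)``.
    """
    path = Path(path)
    payload = json.loads(path.read_text())
    base = _manifest_dir(path, payload)
    window = payload.get("readout_window_nm")
    window = tuple(window) if window else None
    blank_file = payload.get("blank_file")
    if not blank_file:
        raise AssayError(f"{path}: manifest lacks the blank (I0) spectrum")
    blank_path = base / blank_file
    if not blank_path.exists():
        raise AssayError(f"{path}: blank spectrum not found: {blank_path}")
    i0 = peak_intensity(read_spectrum_csv(blank_path), window)
    measurements: dict[str, tuple[float, float]] = {}
    for e in payload.get("entries", []):
        f = base / e["file"]
        if not f.exists():
            raise AssayError(f"{path}: spectrum file not found: {f}")
        i = peak_intensity(read_spectrum_csv(f), window)
        measurements[e["miRNA"]] = (i0, i)
    if not measurements:
        raise AssayError(f"{path}: manifest has no entries")
    return payload.get("probe", path.stem), measurements, payload.get("cognate"), window
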