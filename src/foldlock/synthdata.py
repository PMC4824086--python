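"""Synthetic emission spectra with Stern–Volmer quenching.

Generates the data the assay pipeline consumes — single spectra, titration
series, and specificity panels (including total-RNA-screen mimics) — with a
known ground truth so parameter recovery can be tested end to end without
instrument data.

The emission peak is Gaussian.  Target addition divides the amplitude by
``1 + ksv_true·c`` (static Stern–Volmer quenching, matching the linear
plots the assay fits); non-cognate additions multiply the amplitude by a
*drift* factor instead — drift > 1 emulates the emission increase seen when
non-target total RNA is added.  Noise is multiplicative with a fixed
coefficient of variation, because fluorimeter counts scale with signal.
All stochastic calls are reproducible from the config seed.

What this generator does **not** emulate: spectral shape changes on target
binding, nanocluster species conversion, or matrix effects beyond the
scalar drift.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from .assay import (
    EmissionSpectrum,
    TitrationSeries,
    write_spectrum_csv,
)

__all__ = [
    "SyntheticSpectraConfig",
    "simulate_spectrum",
    "simulate_titration",
    "simulate_specificity_panel",
    "write_titration",
    "write_panel",
]

# Titration range used when none is given: 0 to 1.0 uM.
DEFAULT_TITRATION_M = (0.0, 0.05e-6, 0.1e-6, 0.2e-6, 0.4e-6, 0.6e-6,
                       0.8e-6, 1.0e-6)
# Panel measurements add target and probe at equal 1.5 uM concentrations.
DEFAULT_PANEL_CONC_M = 1.5e-6


@dataclass(frozen=True)
class SyntheticSpectraConfig:
    """Ground truth for the generator.

    Defaults mirror the yellow-emitting miR-21 probe: 580 nm readout under
    480 nm excitation, peak I0 counts of ~3×10⁶, and a Stern–Volmer
    constant that gives I0/I = 9 at the 1.5 μM panel concentration.
    """

    peak_center_nm: float = 580.0
    peak_width_nm: float = 25.0  # Gaussian sigma
    baseline: float = 0.0  # baseline-corrected output; set >0 to study bias
    i0_amplitude: float = 3.0e6
    ksv_true_per_m: float = (9.0 - 1.0) / DEFAULT_PANEL_CONC_M
    noise_cv: float = 0.05
    nontarget_drift: float = 1.0
    excitation_nm: float = 480.0
    wl_start_nm: float = 450.0
    wl_stop_nm: float = 750.0
    wl_step_nm: float = 2.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.peak_width_nm <= 0:
            raise ValueError("peak_width_nm must be > 0")
        if self.i0_amplitude <= 0:
            raise ValueError("i0_amplitude must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.nontarget_drift < 0:
            raise ValueError("nontarget_drift must be >= 0")
        if self.noise_cv > 0 and self.seed is None:
            raise ValueError("a seed is mandatory for stochastic simulation")

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return np.arange(self.wl_start_nm, self.wl_stop_nm + self.wl_step_nm,
                         self.wl_step_nm)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _gaussian_trace(config: SyntheticSpectraConfig, amplitude: float,
                    rng: np.random.Generator | None) -> np.ndarray:
    w = config.wavelengths_nm
    y = config.baseline + amplitude * np.exp(
        -0.5 * ((w - config.peak_center_nm) / config.peak_width_nm) ** 2
    )
    if config.noise_cv > 0:
        if rng is None:
            rng = config.rng()
        y = y * (1.0 + config.noise_cv * rng.standard_normal(y.size))
    return np.clip(y, 0.0, None)


def simulate_spectrum(
    config: SyntheticSpectraConfig,
    concentration_m: float,
    rng: np.random.Generator | None = None,
    label: str = "",
) -> EmissionSpectrum:
    """One emission scan at the given cognate target concentration.

    The Gaussian amplitude is ``i0_amplitude / (1 + ksv_true·c)``.  Without
    an explicit ``rng`` the config seed is used, so identical calls yield
    bit-identical spectra.
    """
    if concentration_m < 0:
        raise ValueError("concentration must be >= 0")
    amp = config.i0_amplitude / (1.0 + config.ksv_true_per_m * concentration_m)
    y = _gaussian_trace(config, amp, rng)
    return EmissionSpectrum(
        wavelengths_nm=config.wavelengths_nm,
        intensities=y,
        excitation_nm=config.excitation_nm,
        label=label or f"c={concentration_m:g}M",
    )


def simulate_titration(
    config: SyntheticSpectraConfig,
    concentrations_m: Sequence[float] = DEFAULT_TITRATION_M,
    probe: str = "synthetic-probe",
) -> TitrationSeries:
    """One spectrum per concentration; must include the zero (I0) point."""
    concs = list(concentrations_m)
    if not concs:
        raise ValueError("empty concentration list")
    if 0.0 not in concs:
        raise ValueError("titration must include the zero (I0) concentration")
    rng = config.rng() if config.noise_cv > 0 else None
    spectra = [
        simulate_spectrum(config, c, rng=rng, label=f"{probe}_c{i}")
        for i, c in enumerate(concs)
    ]
    half = 2.354 * config.peak_width_nm / 2.0  # FWHM/2 readout window
    return TitrationSeries(
        probe=probe,
        concentrations_m=np.array(concs),
        spectra=spectra,
        readout_window_nm=(config.peak_center_nm - half,
                           config.peak_center_nm + half),
    )


def simulate_specificity_panel(
    config: SyntheticSpectraConfig,
    panel_ids: Sequence[str],
    cognate_id: str,
    concentration_m: float = DEFAULT_PANEL_CONC_M,
    cognate_ksv_per_m: float | None = None,
) -> tuple[dict[str, EmissionSpectrum], EmissionSpectrum]:
    """Spectra for a specificity panel plus the blank (no addition) scan.

    The cognate entry is quenched by the Stern–Volmer law at
    ``concentration_m``; every other entry keeps the I0 amplitude times the
    ``nontarget_drift`` factor (drift > 1 → apparent I0/I < 1).
    """
    if not panel_ids:
        raise ValueError("empty specificity panel")
    ksv = cognate_ksv_per_m if cognate_ksv_per_m is not None else config.ksv_true_per_m
    rng = config.rng() if config.noise_cv > 0 else None
    blank = EmissionSpectrum(
        wavelengths_nm=config.wavelengths_nm,
        intensities=_gaussian_trace(config, config.i0_amplitude, rng),
        excitation_nm=config.excitation_nm,
        label="blank",
    )
    spectra: dict[str, EmissionSpectrum] = {}
    for mirna in panel_ids:
        if mirna == cognate_id:
            amp = config.i0_amplitude / (1.0 + ksv * concentration_m)
        else:
            amp = config.i0_amplitude * config.nontarget_drift
        spectra[mirna] = EmissionSpectrum(
            wavelengths_nm=config.wavelengths_nm,
            intensities=_gaussian_trace(config, amp, rng),
            excitation_nm=config.excitation_nm,
            label=mirna,
        )
    return spectra, blank


# ---------------------------------------------------------------------------
# Writers emitting the CSV + JSON manifest dialect the assay module reads
# ---------------------------------------------------------------------------


def write_titration(
    config: SyntheticSpectraConfig,
    out_dir: str | Path,
    concentrations_m: Sequence[float] = DEFAULT_TITRATION_M,
    probe: str = "synthetic-probe",
) -> Path:
    """Write a simulated titration; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    series = simulate_titration(config, concentrations_m, probe=probe)
    entries = []
    for i, (c, spec) in enumerate(zip(series.concentrations_m, series.spectra)):
        fname = f"spectrum_{i:02d}.csv"
        write_spectrum_csv(spec, out_dir / fname)
        entries.append({"file": fname, "concentration_m": float(c)})
    manifest: dict[str, Any] = {
        "schema_version": "1",
        "probe": probe,
        "excitation_nm": config.excitation_nm,
        "readout_window_nm": list(series.readout_window_nm),
        "ksv_true_per_m": config.ksv_true_per_m,
        "seed": config.seed,
        "entries": entries,
    }
    path = out_dir / "titration_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def write_panel(
    config: SyntheticSpectraConfig,
    out_dir: str | Path,
    panel_ids: Sequence[str],
    cognate_id: str,
    probe: str = "synthetic-probe",
    concentration_m: float = DEFAULT_PANEL_CONC_M,
) -> Path:
    """Write a simulated specificity panel; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spectra, blank = simulate_specificity_panel(
        config, panel_ids, cognate_id, concentration_m=concentration_m
    )
    write_spectrum_csv(blank, out_dir / "blank.csv")
    entries = []
    for mirna, spec in spectra.items():
        fname = f"panel_{mirna.replace('/', '_')}.csv"
        write_spectrum_csv(spec, out_dir / fname)
        entries.append({"miRNA": mirna, "file": fname})
    half = 2.354 * config.peak_width_nm / 2.0
    manifest: dict[str, Any] = {
        "schema_version": "1",
        "probe": probe,
        "cognate": cognate_id,
        "blank_file": "blank.csv",
        "readout_window_nm": [config.peak_center_nm - half,
                              config.peak_center_nm + half],
        "concentration_m": concentration_m,
        "nontarget_drift": config.nontarget_drift,
        "seed": config.seed,
        "entries": entries,
    }
    path = out_dir / "panel_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
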