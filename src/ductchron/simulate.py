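"""Synthetic cores with known ground truth.

The generator emulates the data structures of a real study — a Tucson
RWL ring-width series plus a sentinel-delimited ImageJ measurement file
per core — with a simple but realistic statistical structure:

* ring widths follow a negative-exponential age trend with AR(1) noise
  (the classic shape of raw conifer ring-width series),
* the number of ducts in a ring is Poisson with mean λ × ring area, so
  the generative rate λ *is* the expected duct density (count · mm⁻²),
* duct areas are lognormal, truncated below at a minimum plausible size
  so no duct can be mistaken for a sentinel after file rounding,
* missing rings are injected with a small probability (zero width, zero
  ducts, and an extra sentinel in the measurement stream).

Defaults are tuned for a 5.15 mm core so roughly 10-20% of years are
ductless — the zero-inflation a real small-diameter core exhibits.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .imagej import IN2_TO_MM2
from .rwl_io import RingWidthCollection, RingWidthSeries, write_rwl

#: Decimal places used when writing duct areas (in in²) to fixture TXT files.
TXT_DECIMALS = 6

#: Half of one least-significant unit of the TXT encoding, in mm² — the
#: worst-case area error a round trip through a fixture file can introduce.
TXT_AREA_TOL_MM2 = 0.5 * 10.0**-TXT_DECIMALS * IN2_TO_MM2


@dataclass(frozen=True)
class CoreParams:
    """Generative parameters for one synthetic core.

    Parameters
    ----------
    n_years : int
        Number of rings (years) to simulate.
    first_year : int
        Calendar year of the innermost ring.
    initial_width_mm : float
        Ring width at the pith before noise (mm).
    decay_rate : float
        Negative-exponential age-trend rate (yr⁻¹); width trend is
        ``initial_width_mm * exp(-decay_rate * t)``.
    ar_coef : float
        AR(1) coefficient of the width noise, in (-1, 1).
    noise_sd_mm : float
        Innovation standard deviation of the width noise (mm).
    duct_rate_per_mm2 : float
        λ — expected ducts per mm² of ring area (the true duct density).
    lognorm_mu, lognorm_sigma : float
        Parameters of the lognormal duct-area distribution (log-mm² scale).
    min_duct_area_mm2 : float
        Truncation floor for duct areas; keeps every synthetic duct
        distinguishable from a sentinel after TXT rounding.
    missing_ring_prob : float
        Per-year probability of an injected missing ring.
    core_width_mm : float
        Core diameter used to turn ring width into ring area.
    """

    n_years: int = 80
    first_year: int = 1940
    initial_width_mm: float = 3.0
    decay_rate: float = 0.02
    ar_coef: float = 0.5
    noise_sd_mm: float = 0.4
    duct_rate_per_mm2: float = 0.15
    lognorm_mu: float = -3.3
    lognorm_sigma: float = 0.5
    min_duct_area_mm2: float = 0.005
    missing_ring_prob: float = 0.02
    core_width_mm: float = 5.15

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise ValidationError("n_years must be >= 1")
        if not -1 < self.ar_coef < 1:
            raise ValidationError("ar_coef must be in (-1, 1)")
        for name in ("initial_width_mm", "noise_sd_mm", "core_width_mm",
                     "lognorm_sigma", "min_duct_area_mm2"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("decay_rate", "duct_rate_per_mm2"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if not 0 <= self.missing_ring_prob < 1:
            raise ValidationError("missing_ring_prob must be in [0, 1)")


@dataclass
class SyntheticCoreTruth:
    """Ground truth for one simulated core.

    ``ring_widths_mm[k]`` and ``ducts_per_year[k]`` describe year
    ``first_year + k``; injected missing rings have zero width and an
    empty duct list.
    """

    sample_id: str
    first_year: int
    ring_widths_mm: list[float]
    ducts_per_year: list[list[float]]
    params: CoreParams
    seed: int
    missing_years: list[int] = field(default_factory=list)

    @property
    def n_ducts(self) -> int:
        return sum(len(d) for d in self.ducts_per_year)

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.ring_widths_mm) - 1


def simulate_core(
    params: CoreParams, seed: int, sample_id: str = "SYN001a"
) -> SyntheticCoreTruth:
    """Simulate one core; fully reproducible under ``seed``."""
    rng = np.random.default_rng(seed)
    t = np.arange(params.n_years)
    trend = params.initial_width_mm * np.exp(-params.decay_rate * t)
    noise = np.empty(params.n_years)
    e = 0.0
    for i in range(params.n_years):
        e = params.ar_coef * e + rng.normal(0.0, params.noise_sd_mm)
        noise[i] = e
    # quantize to the 0.01 mm dialect so fixture RWL files are lossless
    widths = np.round(np.maximum(0.0, trend + noise), 2)

    missing = rng.random(params.n_years) < params.missing_ring_prob
    widths[missing] = 0.0

    ducts: list[list[float]] = []
    for i in range(params.n_years):
        ring_area = widths[i] * params.core_width_mm
        count = rng.poisson(params.duct_rate_per_mm2 * ring_area) if ring_area > 0 else 0
        areas = []
        while len(areas) < count:
            a = float(rng.lognormal(params.lognorm_mu, params.lognorm_sigma))
            if a >= params.min_duct_area_mm2:
                areas.append(a)
        ducts.append(areas)

    return SyntheticCoreTruth(
        sample_id=sample_id,
        first_year=params.first_year,
        ring_widths_mm=[float(w) for w in widths],
        ducts_per_year=ducts,
        params=params,
        seed=seed,
        missing_years=[params.first_year + int(i) for i in np.flatnonzero(missing)],
    )


def estimate_duct_rate(
    ring_area_mm2: "np.ndarray", duct_production: "np.ndarray"
) -> tuple[float, float]:
    """Estimate λ (ducts per mm²) by regression through the origin.

    Returns ``(lambda_hat, se)`` from the through-origin least-squares fit
    of duct production on ring area. The standard error is the
    heteroskedasticity-robust (sandwich) estimate: counts are
    Poisson-like, so their variance grows with ring area and the
    homoskedastic OLS formula would understate the uncertainty.
    """
    x = np.asarray(ring_area_mm2, dtype=float)
    y = np.asarray(duct_production, dtype=float)
    sxx = float((x * x).sum())
    if sxx == 0:
        raise ValidationError("all ring areas are zero; rate is unidentifiable")
    lam_hat = float((x * y).sum() / sxx)
    resid = y - lam_hat * x
    se = float(np.sqrt((x**2 * resid**2).sum()) / sxx)
    return lam_hat, se


def truth_sentinel_stream(truth: SyntheticCoreTruth) -> list[float]:
    """The in² measurement stream a perfect operator would record.

    Each year's duct areas (converted to in², rounded as the file will
    be) followed by one sentinel zero; a ductless or missing year
    contributes a bare sentinel.
    """
    stream: list[float] = []
    for areas in truth.ducts_per_year:
        stream.extend(round(a / IN2_TO_MM2, TXT_DECIMALS) for a in areas)
        stream.append(0.0)
    return stream


def emit_fixture_files(
    truth: SyntheticCoreTruth, out_dir: str | Path, precision: float = 0.01
) -> tuple[Path, Path]:
    """Write the ImageJ-style TXT and Tucson RWL files for one core.

    Returns ``(txt_path, rwl_path)``. Round-tripping the pair through
    the full pipeline recovers per-year duct counts exactly and duct
    areas to TXT rounding precision.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    txt_path = out_dir / f"{truth.sample_id}.txt"
    with txt_path.open("w", encoding="utf-8") as fh:
        fh.write(" \tLabel\tArea\n")
        for i, area in enumerate(truth_sentinel_stream(truth), start=1):
            fh.write(f"{i}\t{truth.sample_id}.tif\t{area:.{TXT_DECIMALS}f}\n")
    rwl_path = out_dir / f"{truth.sample_id}.rwl"
    series = RingWidthSeries(
        sample_id=truth.sample_id,
        first_year=truth.first_year,
        widths=truth.ring_widths_mm,
        precision=precision,
    )
    coll = RingWidthCollection()
    coll.add(series)
    write_rwl(coll, rwl_path, precision=precision)
    return txt_path, rwl_path


def emit_site(
    truths: list[SyntheticCoreTruth], out_dir: str | Path, precision: float = 0.01
) -> tuple[list[Path], Path]:
    """Write per-core TXT files plus one site RWL holding every series."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    txt_paths = []
    coll = RingWidthCollection()
    for truth in truths:
        txt, _ = emit_fixture_files(truth, out_dir, precision=precision)
        txt_paths.append(txt)
        (out_dir / f"{truth.sample_id}.rwl").unlink()  # single site file instead
        coll.add(
            RingWidthSeries(
                truth.sample_id, truth.first_year, truth.ring_widths_mm, precision
            )
        )
    rwl_path = out_dir / "site.rwl"
    write_rwl(coll, rwl_path, precision=precision)
    return txt_paths, rwl_path


def write_truth_json(truths: list[SyntheticCoreTruth], path: str | Path) -> None:
    """Persist ground truth (widths, duct lists, parameters) for tests."""
    payload = []
    for t in truths:
        d = dataclasses.asdict(t)
        d["params"] = dataclasses.asdict(t.params)
        payload.append(d)
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")
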