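"""Cold-stage droplet-freezing statistics under the singular (site-specific)
model.

Each droplet freezes at the characteristic temperature of its most active
site; the number of sites active above T in a droplet is Poisson with mean
λ(T), so the fraction frozen obeys f(T) = 1 − exp(−λ(T)) and the cumulative
number of nucleation sites per substrate molecule is

    n_mol(T) = −ln(1 − f(T)) / X,

with X the number of substrate molecules per droplet.  Confidence bands are
Monte-Carlo: events are binned in 0.5 K intervals, the observed count in
each bin is taken as a Poisson mean, replicate event tables are drawn and
re-accumulated into n_mol replicates, and the band is the 10th–90th
percentile of the replicates (1000 draws by default).

Temperatures in assay tables are °C; grids are descending from T_start.
Censored droplets (unfrozen at the end of the ramp) stay in the denominator
of f.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class FreezingAssayData:
    """Droplet records plus assay metadata.

    ``records`` columns: droplet_id (int), t_freeze (°C, NaN when censored),
    censored (bool).
    """

    records: pd.DataFrame
    molecules_per_droplet: float
    droplet_volume_ul: float = 30.0
    t_start: float = 0.0
    t_end: float = -30.0
    cooling_rate: float = 1.0          # K/min
    temperature_uncertainty: float = 0.2

    def __post_init__(self) -> None:
        req = {"droplet_id", "t_freeze", "censored"}
        if not req.issubset(self.records.columns):
            raise ValueError(f"records must have columns {sorted(req)}")
        if self.molecules_per_droplet <= 0:
            raise ValueError("molecules_per_droplet must be positive")
        tf = self.records.loc[~self.records.censored, "t_freeze"]
        if len(tf) and (tf.max() > self.t_start + 1e-9 or tf.min() < self.t_end - 1e-9):
            raise ValueError("freezing temperatures fall outside the cooling ramp")

    @property
    def n_droplets(self) -> int:
        return len(self.records)

    @property
    def freeze_temps(self) -> np.ndarray:
        return self.records.loc[~self.records.censored, "t_freeze"].to_numpy(dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return self.records.copy()

    @classmethod
    def from_frame(cls, df: pd.DataFrame, molecules_per_droplet: float, **kw):
        df = df.copy()
        if "censored" not in df.columns:
            df["censored"] = df["t_freeze"].isna()
        return cls(df, molecules_per_droplet, **kw)


@dataclass
class NmolCurve:
    """n_mol(T) on a descending grid, with an MC confidence band.

    ``valid`` is False where f = 1 (n_mol undefined; never ±inf) or where a
    background-subtraction flag applies.
    """

    grid: np.ndarray                   # °C, descending
    fraction_frozen: np.ndarray
    n_mol: np.ndarray                  # NaN where invalid
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    valid: np.ndarray
    bin_width: float = 0.5
    n_draws: int = 0
    percentiles: tuple = (10.0, 90.0)
    seed: int | None = None
    flags: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.flags is None:
            self.flags = np.zeros(len(self.grid), dtype=bool)


def make_grid(t_start: float = 0.0, t_end: float = -30.0, bin_width: float = 0.5) -> np.ndarray:
    """Descending temperature grid of bin edges (°C), t_start excluded,
    t_end included: each point is the cold edge of one bin."""
    n = int(round((t_start - t_end) / bin_width))
    return t_start - bin_width * np.arange(1, n + 1)


# --------------------------------------------------------------------------- #
# core statistics
# --------------------------------------------------------------------------- #


def fraction_frozen(assay: FreezingAssayData, grid=None) -> tuple:
    """f(T) = #droplets frozen at or above T / total droplets (censored
    droplets stay in the denominator).  Returns (grid, f)."""
    if assay.n_droplets == 0:
        raise ValueError("empty assay")
    if grid is None:
        grid = make_grid(assay.t_start, assay.t_end)
    grid = np.asarray(grid, dtype=float)
    tf = assay.freeze_temps
    f = np.array([(tf >= t - 1e-12).sum() for t in grid], dtype=float) / assay.n_droplets
    return grid, f


def nmol(f, molecules_per_droplet: float) -> tuple:
    """n_mol = −ln(1 − f)/X.  Where f = 1 the value is undefined: the curve
    is NaN there and flagged invalid (never ±inf)."""
    f = np.asarray(f, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("fraction frozen must lie in [0, 1]")
    valid = f < 1.0
    out = np.full_like(f, np.nan)
    out[valid] = -np.log1p(-f[valid]) / molecules_per_droplet
    return out, valid


def bin_event_counts(assay: FreezingAssayData, grid) -> np.ndarray:
    """Events per temperature bin; bin i covers (grid[i]+Δ, grid[i]] going
    down in temperature (left-closed at the cold edge)."""
    grid = np.asarray(grid, dtype=float)
    bw = grid[0] - grid[1] if len(grid) > 1 else 0.5
    tf = assay.freeze_temps
    counts = np.zeros(len(grid), dtype=np.int64)
    for t in tf:
        # first grid point at or below the freezing temperature
        i = int(np.searchsorted(-grid, -t - 1e-12))
        i = min(i, len(grid) - 1)
        counts[i] += 1
    return counts


def poisson_mc_ci(assay: FreezingAssayData, bin_width: float = 0.5,
                  n_draws: int = 1000, percentiles: tuple = (10.0, 90.0),
                  seed: int | None = None, grid=None) -> NmolCurve:
    """Monte-Carlo confidence band for n_mol(T).

    Observed per-bin event counts are taken as Poisson means; ``n_draws``
    replicate event tables are accumulated into n_mol replicates and the band
    is the stated percentile pair at each grid point.  Replicates in which
    the cumulative count reaches the droplet total have f = 1 there: those
    points are undefined within the replicate and are excluded (NaN-aware
    percentiles); grid points where more than half the replicates are
    undefined are flagged.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if n_draws < 2:
        raise ValueError("need at least 2 draws")
    if grid is None:
        grid = make_grid(assay.t_start, assay.t_end, bin_width)
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    counts = bin_event_counts(assay, grid)
    n = assay.n_droplets
    x = assay.molecules_per_droplet

    _, f_obs = fraction_frozen(assay, grid)
    nm_obs, valid = nmol(f_obs, x)

    reps = rng.poisson(lam=np.broadcast_to(counts, (n_draws, len(grid))))
    cum = np.minimum(np.cumsum(reps, axis=1), n)
    f_rep = cum / n
    nm_rep = np.where(f_rep < 1.0, -np.log1p(-np.clip(f_rep, 0, 1 - 1e-15)) / x, np.nan)
    with np.errstate(invalid="ignore"):
        lo = np.nanpercentile(nm_rep, percentiles[0], axis=0)
        hi = np.nanpercentile(nm_rep, percentiles[1], axis=0)
    undef_frac = np.mean(np.isnan(nm_rep), axis=0)
    flags = undef_frac > 0.5
    lo = np.where(np.isnan(nm_obs), np.nan, np.minimum(lo, nm_obs))
    hi = np.where(np.isnan(nm_obs), np.nan, np.maximum(hi, nm_obs))
    return NmolCurve(grid, f_obs, nm_obs, lo, hi, valid & ~flags, bin_width,
                     n_draws, tuple(percentiles), seed, flags)


def subtract_background(sample: NmolCurve, background: NmolCurve) -> NmolCurve:
    """Background subtraction on differential (per-bin) site spectra.

    Both curves must share a grid and be normalised per the same unit (the
    caller scales a per-droplet background to per-molecule before calling).
    Differential spectra are subtracted bin-by-bin, floored at zero,
    re-accumulated; bins where background ≥ sample are flagged.
    """
    if len(sample.grid) != len(background.grid) or not np.allclose(sample.grid, background.grid):
        raise ValueError("sample and background grids differ")

    def diff(curve):
        nm = np.where(np.isnan(curve.n_mol), np.nan, curve.n_mol)
        d = np.diff(np.concatenate([[0.0], np.nan_to_num(nm, nan=np.nan)]))
        return d

    ds = diff(sample)
    db = diff(background)
    with np.errstate(invalid="ignore"):
        corrected = ds - db
        flagged = (db >= ds) & (db > 0)
        corrected = np.where(corrected < 0, 0.0, corrected)
    out = np.nancumsum(corrected)
    out = np.where(np.isnan(sample.n_mol), np.nan, out)
    lo = np.where(np.isnan(sample.ci_lower), np.nan,
                  np.maximum(sample.ci_lower - (sample.n_mol - out), 0.0))
    hi = np.where(np.isnan(sample.ci_upper), np.nan,
                  np.maximum(sample.ci_upper - (sample.n_mol - out), 0.0))
    return NmolCurve(sample.grid.copy(), sample.fraction_frozen.copy(), out,
                     lo, hi, sample.valid & ~flagged, sample.bin_width,
                     sample.n_draws, sample.percentiles, sample.seed, flagged)


# --------------------------------------------------------------------------- #
# table I/O
# --------------------------------------------------------------------------- #


def read_assay_table(path, molecules_per_droplet: float, **kw) -> FreezingAssayData:
    """Delimited text with columns droplet_id, t_freeze, censored."""
    with open(path) as fh:
        head = fh.readline()
    sep = "," if "," in head else r"\s+"
    df = pd.read_csv(path, sep=sep, comment="#")
    df["censored"] = df.get("censored", df["t_freeze"].isna()).astype(bool)
    df.loc[df.censored, "t_freeze"] = np.nan
    return FreezingAssayData(df, molecules_per_droplet, **kw)


def write_assay_table(assay: FreezingAssayData, path) -> None:
    assay.records.to_csv(path, index=False)
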