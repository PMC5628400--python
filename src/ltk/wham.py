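"""1D weighted-histogram analysis of umbrella-sampling windows.

Given biased samples of a reaction coordinate x (here, a ligand-site
distance in angstrom) from windows restrained by harmonic potentials at
staggered centers, WHAM solves the self-consistent equations

    p_j = ( sum_i n_ij ) / ( sum_i N_i exp[(f_i - U_i(x_j)) / kT] )
    f_i = -kT ln sum_j p_j exp(-U_i(x_j) / kT)

for the unbiased bin probabilities p_j and per-window free-energy
constants f_i, then reports F_j = -kT ln p_j anchored so min F = 0.
Bootstrap resampling of each window's samples yields per-bin
uncertainties; adjacent-window histogram overlap diagnoses sampling gaps.

A deliberately explicit ``bias_convention`` flag distinguishes the
restraint form U = k (x - x0)^2 written by AMBER-style engines ("full")
from U = (1/2) k (x - x0)^2 assumed by the Grossfield WHAM code ("half");
mixing the two silently halves or doubles every bias and visibly distorts
the recovered profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .synthetic import KB_KCAL

logger = logging.getLogger(__name__)

__all__ = [
    "UmbrellaWindow",
    "PMFProfile",
    "OverlapReport",
    "ConvergenceError",
    "bias_factor",
    "load_window_data",
    "write_window_data",
    "wham_solve",
    "bootstrap_pmf",
    "histogram_overlap",
]


def bias_factor(convention: str) -> float:
    """Prefactor c in U_bias = c * k * (x - x0)^2 for a named convention."""
    try:
        return {"full": 1.0, "half": 0.5}[convention]
    except KeyError:
        raise ValueError(
            f"unknown bias convention {convention!r}; use 'full' or 'half'"
        ) from None


class ConvergenceError(RuntimeError):
    """WHAM iteration failed to reach tolerance; carries the residual."""

    def __init__(self, residual: float, max_iter: int):
        self.residual = residual
        super().__init__(
            f"WHAM did not converge within {max_iter} iterations "
            f"(final max |df| = {residual:.3e} kcal/mol)"
        )


@dataclass
class UmbrellaWindow:
    """Biased samples from one harmonic umbrella window."""

    samples: np.ndarray
    center: float
    force_constant: float
    bias_convention: str = "half"
    temperature: float = 300.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.force_constant <= 0:
            raise ValueError("force_constant must be > 0")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("window samples must be finite")
        bias_factor(self.bias_convention)

    @property
    def n_samples(self) -> int:
        return self.samples.size

    def bias_energy(self, x: np.ndarray) -> np.ndarray:
        c = bias_factor(self.bias_convention)
        return c * self.force_constant * (np.asarray(x, float) - self.center) ** 2


@dataclass
class PMFProfile:
    """A binned free-energy profile with optional bootstrap uncertainties.

    ``free_energy`` is NaN in bins that received no samples (empty bins are
    reported as missing, never as silent zeros), and is anchored so the
    minimum over covered bins is zero.
    """

    bin_centers: np.ndarray
    free_energy: np.ndarray
    uncertainty: np.ndarray | None = None
    window_offsets: np.ndarray | None = None
    temperature: float = 300.0

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.free_energy = np.asarray(self.free_energy, dtype=float)
        if np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("bin_centers must be strictly increasing")
        if self.uncertainty is not None:
            self.uncertainty = np.asarray(self.uncertainty, dtype=float)
            if np.nanmin(self.uncertainty) < 0:
                raise ValueError("uncertainty must be >= 0")

    @property
    def covered(self) -> np.ndarray:
        """Boolean mask of bins that received samples."""
        return np.isfinite(self.free_energy)

    def to_csv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        import pandas as pd

        df = pd.DataFrame(
            {
                "bin_center": self.bin_centers,
                "free_energy_kcal_mol": self.free_energy,
                "uncertainty_kcal_mol": (
                    self.uncertainty
                    if self.uncertainty is not None
                    else np.full_like(self.free_energy, np.nan)
                ),
            }
        )
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            df.to_csv(fh, index=False)


@dataclass
class OverlapReport:
    """Histogram overlap between adjacent umbrella windows."""

    pairs: list[tuple[int, int]]
    overlaps: np.ndarray
    bin_centers: np.ndarray
    total_counts: np.ndarray
    flagged: list[tuple[int, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# file I/O in the standard umbrella-window convention


def write_window_data(
    windows: Sequence[UmbrellaWindow],
    directory: str | Path,
    prefix: str = "window",
) -> Path:
    """Write per-window time series plus a metadata file.

    The metadata file lists ``path  center  spring_constant`` per window
    (the convention of the standard WHAM post-processing codes) and
    records the bias convention in a header flag so a round-trip load
    reconstructs the same biased model.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta_path = directory / f"{prefix}_metadata.txt"
    conventions = {w.bias_convention for w in windows}
    if len(conventions) > 1:
        raise ValueError("all windows in one metadata file must share a bias convention")
    temperature = windows[0].temperature if windows else 300.0
    with open(meta_path, "w") as meta:
        meta.write(f"# bias_convention: {next(iter(conventions)) if conventions else 'half'}\n")
        meta.write(f"# temperature: {temperature}\n")
        for i, w in enumerate(windows):
            series = directory / f"{prefix}_{i:03d}.txt"
            with open(series, "w") as fh:
                for t, x in enumerate(w.samples):
                    fh.write(f"{t:d}\t{x:.17g}\n")
            meta.write(f"{series.name}\t{w.center:.17g}\t{w.force_constant:.17g}\n")
    return meta_path


def load_window_data(
    metadata_path: str | Path,
    bias_convention: str | None = None,
) -> list[UmbrellaWindow]:
    """Load umbrella windows from a metadata file plus time-series files.

    Metadata lines are ``path  center  spring_constant``; series files are
    two columns (time, x).  The bias convention is read from a
    ``# bias_convention:`` header flag when present; files without the
    flag default to "half" (the convention of the external WHAM package),
    and an explicit ``bias_convention`` argument overrides both.
    """
    metadata_path = Path(metadata_path)
    header_convention = None
    temperature = 300.0
    windows = []
    with open(metadata_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("bias_convention:"):
                    header_convention = body.split(":", 1)[1].strip()
                elif body.lower().startswith("temperature:"):
                    temperature = float(body.split(":", 1)[1])
                continue
            if not line:
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(
                    f"{metadata_path}:{lineno}: expected 'path center spring', got {line!r}"
                )
            series_path = metadata_path.parent / fields[0]
            if not series_path.exists():
                raise FileNotFoundError(
                    f"{metadata_path}:{lineno}: time-series file not found: {series_path}"
                )
            center, spring = float(fields[1]), float(fields[2])
            samples = []
            with open(series_path) as sf:
                for sno, srow in enumerate(sf, start=1):
                    srow = srow.strip()
                    if not srow or srow.startswith("#"):
                        continue
                    parts = srow.split()
                    try:
                        samples.append(float(parts[1]))
                    except (IndexError, ValueError):
                        raise ValueError(
                            f"{series_path}:{sno}: non-numeric or malformed row {srow!r}"
                        ) from None
            convention = bias_convention or header_convention or "half"
            windows.append(
                UmbrellaWindow(
                    samples=np.array(samples),
                    center=center,
                    force_constant=spring,
                    bias_convention=convention,
                    temperature=temperature,
                )
            )
    logger.info(
        "loaded %d windows from %s (bias convention %s)",
        len(windows), metadata_path,
        bias_convention or header_convention or "half (default)",
    )
    return windows


# ---------------------------------------------------------------------------
# the WHAM solver


def _anchor(values: np.ndarray, mode: str) -> np.ndarray:
    if mode == "min":
        return values - np.nanmin(values)
    if mode == "mean":
        return values - np.nanmean(values)
    raise ValueError(f"unknown anchor mode {mode!r}")


def wham_solve(
    windows: Sequence[UmbrellaWindow],
    n_bins: int | None = None,
    x_range: tuple[float, float] | None = None,
    temperature: float = 300.0,
    tol: float = 1e-6,
    max_iter: int = 100_000,
    anchor: str = "min",
) -> PMFProfile:
    """Solve the WHAM self-consistency equations on a uniform bin grid.

    Defaults: bins span the pooled sample range with 4 bins per window;
    convergence when max |delta f_i| < ``tol`` kcal/mol.  Bins with no
    samples get NaN free energy and are excluded from anchoring.
    """
    if not windows:
        raise ValueError("need at least one window")
    kt = KB_KCAL * temperature
    if n_bins is None:
        n_bins = max(10, 4 * len(windows))
    if x_range is None:
        pooled_min = min(w.samples.min() for w in windows)
        pooled_max = max(w.samples.max() for w in windows)
        x_range = (pooled_min, pooled_max)
    edges = np.linspace(x_range[0], x_range[1], n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    n_w = len(windows)
    counts = np.zeros((n_w, n_bins))
    for i, w in enumerate(windows):
        counts[i], _ = np.histogram(w.samples, bins=edges)
    n_i = counts.sum(axis=1)  # samples landing in range, per window
    m_j = counts.sum(axis=0)  # total per bin
    covered = m_j > 0

    # bias energies at bin centers, (n_w, n_bins)
    u = np.array([w.bias_energy(centers) for w in windows])
    log_n_i = np.log(np.maximum(n_i, 1e-300))
    log_m_j = np.where(covered, np.log(np.maximum(m_j, 1e-300)), -np.inf)

    f = np.zeros(n_w)
    residual = np.inf
    for _ in range(max_iter):
        # log p_j = log m_j - logsumexp_i [ log N_i + (f_i - u_ij)/kT ]
        log_denom = logsumexp(
            log_n_i[:, None] + (f[:, None] - u) / kt, axis=0
        )
        log_p = log_m_j - log_denom
        # f_i = -kT logsumexp_j [ log p_j - u_ij/kT ]
        with np.errstate(invalid="ignore"):
            f_new = -kt * logsumexp(log_p[None, :] - u / kt, axis=1)
        f_new -= f_new[0]  # gauge fix
        residual = float(np.max(np.abs(f_new - f)))
        f = f_new
        if residual < tol:
            break
    else:
        raise ConvergenceError(residual, max_iter)

    log_denom = logsumexp(log_n_i[:, None] + (f[:, None] - u) / kt, axis=0)
    log_p = log_m_j - log_denom
    free = np.where(covered, -kt * log_p, np.nan)
    free = _anchor(free, anchor)
    return PMFProfile(
        bin_centers=centers,
        free_energy=free,
        window_offsets=f,
        temperature=temperature,
    )


def bootstrap_pmf(
    windows: Sequence[UmbrellaWindow],
    n_boot: int = 50,
    seed: int = 0,
    anchor: str = "min",
    max_failed_fraction: float = 0.10,
    **wham_settings,
) -> PMFProfile:
    """Bootstrap per-bin uncertainties for the WHAM profile.

    Each replicate resamples every window's samples with replacement
    (keeping window sizes), re-solves WHAM, and re-anchors; the reported
    uncertainty is the per-bin standard deviation over replicates while
    the reported free energy is the solution on the original samples.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    base = wham_solve(windows, anchor=anchor, **wham_settings)
    wham_settings.setdefault("n_bins", len(base.bin_centers))
    wham_settings.setdefault(
        "x_range",
        (
            base.bin_centers[0] - 0.5 * (base.bin_centers[1] - base.bin_centers[0]),
            base.bin_centers[-1] + 0.5 * (base.bin_centers[1] - base.bin_centers[0]),
        ),
    )
    rng = np.random.default_rng(seed)
    replicates = []
    failures = 0
    for _ in range(n_boot):
        resampled = [
            UmbrellaWindow(
                samples=rng.choice(w.samples, size=w.n_samples, replace=True),
                center=w.center,
                force_constant=w.force_constant,
                bias_convention=w.bias_convention,
                temperature=w.temperature,
            )
            for w in windows
        ]
        try:
            replicates.append(
                wham_solve(resampled, anchor=anchor, **wham_settings).free_energy
            )
        except ConvergenceError:
            failures += 1
    if failures > max_failed_fraction * n_boot:
        raise RuntimeError(
            f"{failures}/{n_boot} bootstrap replicates failed to converge"
        )
    stack = np.array(replicates)
    with np.errstate(invalid="ignore"):
        sigma = np.nanstd(stack, axis=0, ddof=1)
    return PMFProfile(
        bin_centers=base.bin_centers,
        free_energy=base.free_energy,
        uncertainty=sigma,
        window_offsets=base.window_offsets,
        temperature=base.temperature,
    )


def histogram_overlap(
    windows: Sequence[UmbrellaWindow],
    n_bins: int | None = None,
    x_range: tuple[float, float] | None = None,
    flag_below: float = 0.02,
) -> OverlapReport:
    """Adjacent-window histogram overlap on a common bin grid.

    Overlap of a pair is sum_j min(h_i(j), h_i+1(j)) with h the
    unit-normalized histograms; pairs below ``flag_below`` are flagged as
    sampling gaps.  Windows are taken adjacent in order of their centers.
    """
    if len(windows) < 2:
        raise ValueError("need at least two windows for overlap analysis")
    if n_bins is None:
        n_bins = max(20, 4 * len(windows))
    if x_range is None:
        x_range = (
            min(w.samples.min() for w in windows),
            max(w.samples.max() for w in windows),
        )
    edges = np.linspace(x_range[0], x_range[1], n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    order = np.argsort([w.center for w in windows])
    hists = []
    for idx in order:
        h, _ = np.histogram(windows[idx].samples, bins=edges)
        total = h.sum()
        hists.append(h / total if total else h.astype(float))
    hists = np.array(hists)
    pairs = [(int(order[i]), int(order[i + 1])) for i in range(len(order) - 1)]
    overlaps = np.array(
        [np.minimum(hists[i], hists[i + 1]).sum() for i in range(len(order) - 1)]
    )
    flagged = [p for p, o in zip(pairs, overlaps) if o < flag_below]
    return OverlapReport(
        pairs=pairs,
        overlaps=overlaps,
        bin_centers=centers,
        total_counts=hists.sum(axis=0),
        flagged=flagged,
    )
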