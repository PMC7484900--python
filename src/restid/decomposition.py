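"""Sub-band decomposition of single-channel EEG windows.

Two routes are supported:

* **EMD** — empirical mode decomposition by envelope sifting.  Each intrinsic
  mode function (IMF) is extracted by repeatedly subtracting the mean of the
  cubic-spline envelopes through the local maxima and minima until a
  Cauchy-type standard-deviation criterion is met.  The two IMFs closest to
  the raw signal under the Minkowski distance are retained as sub-bands;
  distant IMFs mostly carry interpolation/end-effect artifacts.
* **DWT** — a three-level biorthogonal 2.2 wavelet cascade, giving the detail
  bands D1, D2, D3 and the level-3 approximation A3 (four sub-bands).  At
  160 Hz these correspond roughly to 40-80, 20-40, 10-20 and 0-10 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.interpolate import CubicSpline
from scipy.spatial.distance import minkowski as _minkowski_distance


@dataclass
class DecompositionConfig:
    method: str = "dwt"                 # "emd" or "dwt"
    minkowski_p: float = 2.0            # IMF-ranking distance order (EMD)
    n_selected_imfs: int = 2
    wavelet: str = "bior2.2"
    levels: int = 3
    sift_sd_threshold: float = 0.2
    max_imfs: int = 10
    max_sift_iters: int = 100

    def __post_init__(self) -> None:
        if self.method not in ("emd", "dwt"):
            raise ValueError(f"unknown decomposition method {self.method!r}")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.n_selected_imfs < 1:
            raise ValueError("n_selected_imfs must be >= 1")
        if self.minkowski_p < 1:
            raise ValueError("minkowski_p must be >= 1")

    @property
    def bands_per_channel(self) -> int:
        return self.n_selected_imfs if self.method == "emd" else self.levels + 1


@dataclass
class SubBandSet:
    bands: list[np.ndarray]
    source_method: str
    band_labels: list[str] = field(default_factory=list)


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima; flat runs count once, at their end."""
    d = np.sign(np.diff(x))
    # propagate slope sign through zero-slope runs so plateaus yield one extremum
    for i in range(1, len(d)):
        if d[i] == 0:
            d[i] = d[i - 1]
    maxima = np.where((d[:-1] > 0) & (d[1:] < 0))[0] + 1
    minima = np.where((d[:-1] < 0) & (d[1:] > 0))[0] + 1
    return maxima, minima


def _envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through extrema, with mirrored-extrema end extension."""
    n = len(x)
    t = idx.astype(float)
    v = x[idx]
    # mirror up to two extrema about each end of the window
    n_mirror = min(2, len(idx))
    t_left = 2 * 0.0 - t[:n_mirror][::-1]
    v_left = v[:n_mirror][::-1]
    t_right = 2 * (n - 1.0) - t[-n_mirror:][::-1]
    v_right = v[-n_mirror:][::-1]
    tt = np.concatenate([t_left, t, t_right])
    vv = np.concatenate([v_left, v, v_right])
    # mirroring can duplicate abscissae when an extremum sits on the boundary
    tt, keep = np.unique(tt, return_index=True)
    vv = vv[keep]
    if len(tt) < 2:
        return np.full(n, vv[0])
    spline = CubicSpline(tt, vv, bc_type="natural")
    return spline(np.arange(n))


def emd(signal: np.ndarray, cfg: DecompositionConfig | None = None
        ) -> tuple[list[np.ndarray], np.ndarray]:
    """Decompose ``signal`` into intrinsic mode functions plus a residual.

    Sifting for each IMF stops when the Cauchy-type criterion
    ``sum((h_prev - h)^2) / sum(h_prev^2) < sift_sd_threshold`` is met or
    ``max_sift_iters`` is exhausted; extraction stops when the residual has
    fewer than two extrema of either kind (monotone remainder) or ``max_imfs``
    is reached.  By construction ``sum(imfs) + residual == signal`` exactly.
    """
    cfg = cfg or DecompositionConfig(method="emd")
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    if len(x) < 8:
        raise ValueError(f"signal too short for EMD (length {len(x)} < 8)")

    imfs: list[np.ndarray] = []
    residual = x.copy()
    for _ in range(cfg.max_imfs):
        maxima, minima = _local_extrema(residual)
        if len(maxima) < 2 or len(minima) < 2:
            break  # monotone (or single-hump) remainder: stop decomposing
        h = residual.copy()
        for _ in range(cfg.max_sift_iters):
            mx, mn = _local_extrema(h)
            if len(mx) < 2 or len(mn) < 2:
                break
            mean_env = 0.5 * (_envelope(h, mx) + _envelope(h, mn))
            h_new = h - mean_env
            denom = float(np.sum(h * h))
            sd = float(np.sum(mean_env * mean_env)) / denom if denom > 0 else 0.0
            h = h_new
            if sd < cfg.sift_sd_threshold:
                break
        imfs.append(h)
        residual = residual - h
    return imfs, residual


def select_imfs_minkowski(signal: np.ndarray, imfs: list[np.ndarray],
                          residual: np.ndarray | None = None,
                          n_selected: int = 2, p: float = 2.0
                          ) -> list[np.ndarray]:
    """Return the ``n_selected`` IMFs closest to ``signal`` in Minkowski distance.

    Output is in ascending-distance order.  If fewer than ``n_selected`` IMFs
    exist the residual is appended (repeatedly if needed) so the downstream
    feature vector keeps a fixed width.
    """
    if not imfs:
        if residual is None:
            raise ValueError("decomposition produced no IMFs and no residual given")
        return [np.asarray(residual, dtype=float)] * n_selected
    x = np.asarray(signal, dtype=float)
    dists = np.array([_minkowski_distance(x, imf, p=p) for imf in imfs])
    order = np.argsort(dists, kind="stable")
    selected = [imfs[i] for i in order[:n_selected]]
    while len(selected) < n_selected:
        if residual is None:
            raise ValueError(
                f"only {len(imfs)} IMFs available, {n_selected} requested, no residual"
            )
        selected.append(np.asarray(residual, dtype=float))
    return selected


def dwt_decompose(signal: np.ndarray, cfg: DecompositionConfig | None = None
                  ) -> SubBandSet:
    """Multi-level DWT returning ``[D1, D2, ..., Dn, An]`` coefficient bands.

    Symmetric signal extension at the boundaries; band lengths follow the
    standard PyWavelets cascade.
    """
    cfg = cfg or DecompositionConfig(method="dwt")
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    wavelet = pywt.Wavelet(cfg.wavelet)
    if len(x) < wavelet.dec_len:
        raise ValueError(
            f"signal length {len(x)} shorter than {cfg.wavelet} filter "
            f"({wavelet.dec_len})"
        )
    coeffs = pywt.wavedec(x, wavelet, level=cfg.levels, mode="symmetric")
    approx, details = coeffs[0], coeffs[1:]  # details ordered Dn..D1
    bands = list(details[::-1]) + [approx]
    labels = [f"D{i}" for i in range(1, cfg.levels + 1)] + [f"A{cfg.levels}"]
    return SubBandSet(bands=bands, source_method="dwt", band_labels=labels)


def decompose(signal: np.ndarray, cfg: DecompositionConfig) -> SubBandSet:
    """Dispatch to EMD (with Minkowski IMF selection) or DWT per ``cfg.method``."""
    if cfg.method == "dwt":
        return dwt_decompose(signal, cfg)
    imfs, residual = emd(signal, cfg)
    selected = select_imfs_minkowski(signal, imfs, residual=residual,
                                     n_selected=cfg.n_selected_imfs,
                                     p=cfg.minkowski_p)
    labels = [f"IMF_{chr(ord('a') + i)}" for i in range(len(selected))]
    return SubBandSet(bands=selected, source_method="emd", band_labels=labels)
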