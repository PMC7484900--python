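"""Per-band features and per-instance feature vectors.

Each sub-band is summarized by four numbers: log10 instantaneous energy,
log10 Teager energy, the Higuchi fractal dimension and the Petrosian fractal
dimension.  With EMD (2 selected IMFs) this yields 8 features per channel,
with DWT (D1, D2, D3, A3) 16 per channel; per-channel blocks are concatenated
in channel-mask order into one vector per instance.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .decomposition import DecompositionConfig, decompose
from .eeg_io import EEGInstance, InstanceSet, common_average_reference

FEATURE_ORDER = ("instantaneous_energy", "teager_energy", "higuchi_fd", "petrosian_fd")


@dataclass
class FeatureConfig:
    higuchi_kmax: int = 10
    log_floor_epsilon: float = 1e-12
    standardize: bool = False  # optional z-scoring, off by default

    def __post_init__(self) -> None:
        if self.higuchi_kmax < 2:
            raise ValueError("higuchi_kmax must be >= 2")
        if self.log_floor_epsilon <= 0:
            raise ValueError("log_floor_epsilon must be positive")


def _check_finite(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite samples")
    return x


def instantaneous_energy(x: np.ndarray, epsilon: float = 1e-12) -> float:
    """log10 mean squared amplitude, floored at ``epsilon``."""
    x = _check_finite(x)
    if len(x) < 1:
        raise ValueError("empty input")
    return float(np.log10(max(np.mean(x * x), epsilon)))


def teager_energy(x: np.ndarray, epsilon: float = 1e-12) -> float:
    """log10 mean Teager-Kaiser operator ``|x_n^2 - x_{n-1} x_{n+1}|``.

    Sensitive to both amplitude and instantaneous frequency; zero (floored)
    for constant and, up to ends, linear signals.
    """
    x = _check_finite(x)
    if len(x) < 3:
        raise ValueError("teager_energy requires at least 3 samples")
    op = np.abs(x[1:-1] ** 2 - x[:-2] * x[2:])
    return float(np.log10(max(np.mean(op), epsilon)))


def higuchi_fd(x: np.ndarray, kmax: int = 10) -> float:
    """Higuchi fractal dimension from the log-log slope of curve lengths.

    For each scale ``k`` the mean normalized length of the ``k`` subsampled
    curves is computed; the FD is the least-squares slope of ``ln L(k)``
    against ``ln(1/k)``.  A line scores ~1, white noise ~2.  Constant input
    (zero curve length) returns 1.0 by convention.
    """
    x = _check_finite(x)
    n = len(x)
    if n < kmax + 1:
        raise ValueError(f"need length >= kmax+1 ({kmax + 1}), got {n}")
    lengths = []
    ks = []
    for k in range(1, kmax + 1):
        lm = []
        for m in range(k):  # offsets m+1..k in 1-based terms
            idx = np.arange(m, n, k)
            if len(idx) < 2:
                continue
            seg = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / ((len(idx) - 1) * k)
            lm.append(seg * norm / k)
        if lm:
            lengths.append(np.mean(lm))
            ks.append(k)
    lengths = np.asarray(lengths)
    if np.all(lengths <= 0):
        return 1.0
    logl = np.log(np.maximum(lengths, 1e-300))
    logk = np.log(1.0 / np.asarray(ks, dtype=float))
    slope = np.polyfit(logk, logl, 1)[0]
    return float(slope) if np.isfinite(slope) else 1.0


def petrosian_fd(x: np.ndarray) -> float:
    """Petrosian fractal dimension from sign changes of the first difference.

    ``log10(N) / (log10(N) + log10(N / (N + 0.4 * n_delta)))`` where
    ``n_delta`` counts strict sign changes (zero differences break no run, so
    monotone and constant signals score exactly 1).
    """
    x = _check_finite(x)
    n = len(x)
    if n < 2:
        raise ValueError("petrosian_fd requires at least 2 samples")
    d = np.diff(x)
    s = np.sign(d)
    s = s[s != 0]
    n_delta = int(np.sum(s[1:] != s[:-1])) if len(s) > 1 else 0
    log_n = np.log10(n)
    return float(log_n / (log_n + np.log10(n / (n + 0.4 * n_delta))))


def band_features(band: np.ndarray, cfg: FeatureConfig) -> np.ndarray:
    """The four features of one sub-band, in the fixed feature order."""
    kmax = min(cfg.higuchi_kmax, len(band) - 1)
    return np.array([
        instantaneous_energy(band, cfg.log_floor_epsilon),
        teager_energy(band, cfg.log_floor_epsilon),
        higuchi_fd(band, kmax),
        petrosian_fd(band),
    ])


def extract_features(instance: EEGInstance, channel_mask: Sequence[int],
                     decomp_cfg: DecompositionConfig,
                     feat_cfg: FeatureConfig | None = None) -> np.ndarray:
    """Feature vector of one instance restricted to ``channel_mask``.

    For each selected channel (in mask order) the channel signal is
    decomposed and each band contributes four features; bands are concatenated
    within a channel, then channels are concatenated.  Length is
    ``len(mask) * bands_per_channel * 4``.
    """
    feat_cfg = feat_cfg or FeatureConfig()
    mask = list(channel_mask)
    if len(mask) == 0:
        raise ValueError("channel_mask selects no channels")
    out = []
    for ch in mask:
        subbands = decompose(instance.data[ch], decomp_cfg)
        for band in subbands.bands:
            out.append(band_features(band, feat_cfg))
    return np.concatenate(out)


@dataclass
class FeatureMatrix:
    """Instances-by-features matrix with per-row subject labels.

    Columns are laid out as contiguous per-channel blocks of width
    ``bands_per_channel * 4`` following ``channel_layout``, which makes
    restriction to a channel subset a pure column slice.
    """

    values: np.ndarray
    subject_ids: list[str]
    channel_layout: list[int]
    method: str
    bands_per_channel: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = len(self.channel_layout) * self.bands_per_channel * 4
        if self.values.shape[1] != expected:
            raise ValueError(
                f"feature width {self.values.shape[1]} != "
                f"{len(self.channel_layout)} channels x {self.bands_per_channel} "
                f"bands x 4"
            )
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("one subject id per row required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def features_per_channel(self) -> int:
        return self.bands_per_channel * 4

    def select_channels(self, channels: Sequence[int]) -> np.ndarray:
        """Column-slice the blocks of the given channels (in given order)."""
        w = self.features_per_channel
        pos = {ch: i for i, ch in enumerate(self.channel_layout)}
        cols = np.concatenate([
            np.arange(pos[ch] * w, (pos[ch] + 1) * w) for ch in channels
        ])
        return self.values[:, cols]

    def to_csv(self, path_or_buf) -> None:
        df = pd.DataFrame(self.values,
                          columns=[f"feature_{j}" for j in range(self.values.shape[1])])
        df.insert(0, "subject_id", self.subject_ids)
        header = (f"# method={self.method} bands_per_channel={self.bands_per_channel} "
                  f"channels={','.join(map(str, self.channel_layout))}\n")
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(header)
            df.to_csv(path_or_buf, index=False)
        else:
            with open(path_or_buf, "w") as f:
                f.write(header)
                df.to_csv(f, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "FeatureMatrix":
        if hasattr(path_or_buf, "read"):
            text = path_or_buf.read()
        else:
            with open(path_or_buf) as f:
                text = f.read()
        header, _, body = text.partition("\n")
        meta = dict(kv.split("=", 1) for kv in header.lstrip("# ").split())
        df = pd.read_csv(io.StringIO(body))
        return cls(
            values=df.drop(columns="subject_id").to_numpy(float),
            subject_ids=df["subject_id"].astype(str).tolist(),
            channel_layout=[int(c) for c in meta["channels"].split(",")],
            method=meta["method"],
            bands_per_channel=int(meta["bands_per_channel"]),
        )


def build_feature_matrix(instances: InstanceSet, decomp_cfg: DecompositionConfig,
                         feat_cfg: FeatureConfig | None = None,
                         apply_car: bool = True) -> FeatureMatrix:
    """Featurize every instance over all channels (the full-channel cache).

    The common average reference is computed per instance over the full
    montage before per-channel decomposition, so cached per-channel blocks
    are identical however many channels a later chromosome selects.
    """
    feat_cfg = feat_cfg or FeatureConfig()
    n_channels = instances[0].n_channels
    layout = list(range(n_channels))
    rows = []
    for inst in instances:
        prepared = common_average_reference(inst) if apply_car else inst
        rows.append(extract_features(prepared, layout, decomp_cfg, feat_cfg))
    values = np.vstack(rows)
    if feat_cfg.standardize:
        mu = values.mean(axis=0)
        sd = values.std(axis=0)
        values = (values - mu) / np.where(sd > 0, sd, 1.0)
    return FeatureMatrix(values=values, subject_ids=instances.subject_ids,
                         channel_layout=layout, method=decomp_cfg.method,
                         bands_per_channel=decomp_cfg.bands_per_channel)
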