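"""Cross-validated NSGA-III channel selection over a featurized cohort.

The optimizer searches a mixed chromosome — one bit per EEG channel plus two
model genes — for trade-offs between three minimized objectives: the number
of selected channels, 1 - TAR and 1 - TRR.  For the 64-channel motor-imagery
montage the LOF chromosome has 66 genes (64 bits, an algorithm code in 1..3
and a neighbor count in 1..10); the OC-SVM variant replaces the two integer
genes with decimals in [0, 1] decoded as nu and gamma.

Because features are channel-separable, the full per-channel feature blocks
are computed once per run and every fitness evaluation is a column slice plus
per-subject model fits — the cache is what makes population-times-generations
many evaluations affordable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .decomposition import DecompositionConfig
from .eeg_io import EEGRecording, segment_instances
from .features import FeatureConfig, FeatureMatrix, build_feature_matrix
from .nsga3 import (Chromosome, Encoding, GeneSpec, TerminationRule,
                    evolve)
from .one_class import (ModelSpec, evaluate_tar_trr, fit_subject_model,
                        spec_from_genes)

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    method: str = "dwt"                   # "emd" or "dwt"
    model_family: str = "lof"             # "lof" or "ocsvm"
    train_fraction: float = 0.8
    n_runs: int = 10
    seeds: Sequence[int] | None = None    # one per run; derived from `seed` if None
    seed: int = 0
    population_size: int = 20
    tolerance: float = 1e-4
    tolerance_period: int = 10
    max_generations: int = 300
    reference_divisions: int = 5
    window_seconds: float = 1.0
    lof_accept_threshold: float = 1.5
    feature: FeatureConfig = field(default_factory=FeatureConfig)

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.seeds is None:
            # spawn one independent stream seed per run, reproducibly
            ss = np.random.SeedSequence(self.seed)
            self.seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                          ss.spawn(self.n_runs)]
        if len(self.seeds) != self.n_runs:
            raise ValueError("need exactly one seed per run")

    @property
    def decomposition(self) -> DecompositionConfig:
        return DecompositionConfig(method=self.method)

    def run_termination(self) -> TerminationRule:
        return TerminationRule(tol=self.tolerance, period=self.tolerance_period,
                               max_gen=self.max_generations)


def lof_encoding(n_channels: int) -> Encoding:
    """64 channel bits + algorithm code (1..3) + neighbor count (1..10)."""
    return Encoding(n_bits=n_channels,
                    genes=(GeneSpec("int", 1, 3), GeneSpec("int", 1, 10)))


def ocsvm_encoding(n_channels: int) -> Encoding:
    """Channel bits + two decimal genes in [0, 1] for nu and gamma."""
    return Encoding(n_bits=n_channels,
                    genes=(GeneSpec("real", 0.0, 1.0), GeneSpec("real", 0.0, 1.0)))


def make_encoding(model_family: str, n_channels: int) -> Encoding:
    return lof_encoding(n_channels) if model_family == "lof" \
        else ocsvm_encoding(n_channels)


def decode_chromosome(chrom: Chromosome, model_family: str,
                      lof_accept_threshold: float = 1.5,
                      rng: np.random.Generator | None = None
                      ) -> tuple[tuple[int, ...], ModelSpec]:
    """Decode a chromosome into (selected channel indices, ModelSpec).

    An all-zero channel mask is repaired in place by setting one random bit
    (logged) so evolution never aborts on a degenerate genotype.
    """
    if not chrom.bits.any():
        rng = rng or np.random.default_rng(0)
        bit = int(rng.integers(len(chrom.bits)))
        chrom.bits[bit] = 1
        logger.warning("all-zero channel mask repaired: set bit %d", bit)
    mask = tuple(int(i) for i in np.flatnonzero(chrom.bits))
    spec = spec_from_genes(model_family, chrom.genes[0], chrom.genes[1],
                           lof_accept_threshold=lof_accept_threshold)
    return mask, spec


def split_cohort(instance_counts: Mapping[str, int], train_fraction: float = 0.8,
                 seed: int | np.random.Generator = 0
                 ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-subject random train/test index split, fixed for a whole run.

    ``instance_counts`` maps subject id to that subject's instance count.
    With 60 instances and fraction 0.8 this gives 48 training and 12 test
    indices.  Train and test are disjoint and jointly exhaustive.
    """
    rng = np.random.default_rng(seed)
    splits = {}
    for sid in instance_counts:
        n = int(instance_counts[sid])
        if n < 5:
            raise ValueError(f"subject {sid} has only {n} instances (need >= 5)")
        n_train = int(round(train_fraction * n))
        n_train = min(max(n_train, 1), n - 1)
        perm = rng.permutation(n)
        splits[sid] = (np.sort(perm[:n_train]), np.sort(perm[n_train:]))
    return splits


class FeatureCache:
    """Full-channel feature matrices per subject, sliced per chromosome."""

    def __init__(self, matrices: Mapping[str, FeatureMatrix]):
        self.matrices = dict(matrices)
        layouts = {tuple(fm.channel_layout) for fm in self.matrices.values()}
        if len(layouts) != 1:
            raise ValueError("all subjects must share one channel layout")
        self.n_channels = len(next(iter(layouts)))

    @classmethod
    def from_cohort(cls, cohort: Sequence[EEGRecording],
                    decomp_cfg: DecompositionConfig,
                    feat_cfg: FeatureConfig | None = None,
                    window_seconds: float = 1.0) -> "FeatureCache":
        matrices = {
            rec.subject_id: build_feature_matrix(
                segment_instances(rec, window_seconds), decomp_cfg, feat_cfg)
            for rec in cohort
        }
        return cls(matrices)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.matrices)

    def instance_counts(self) -> dict[str, int]:
        return {sid: fm.values.shape[0] for sid, fm in self.matrices.items()}

    def sliced(self, sid: str, channels: Sequence[int], rows: np.ndarray
               ) -> np.ndarray:
        return self.matrices[sid].select_channels(channels)[rows]


def evaluate_chromosome(chrom: Chromosome, cache: FeatureCache,
                        splits: Mapping[str, tuple[np.ndarray, np.ndarray]],
                        cfg: ExperimentConfig) -> tuple[float, float, float]:
    """Fitness of one chromosome: ``(n_channels, 1 - TAR, 1 - TRR)``.

    One model per subject is fitted on that subject's training rows restricted
    to the decoded channel mask and scored against the subject's genuine test
    rows and every other subject's test rows.  A model-fit failure scores the
    chromosome as worst-case ``(n_channels, 1, 1)``.
    """
    mask, spec = decode_chromosome(chrom, cfg.model_family,
                                   cfg.lof_accept_threshold)
    try:
        models = {}
        genuine = {}
        for sid in cache.subject_ids:
            train_idx, test_idx = splits[sid]
            models[sid] = fit_subject_model(cache.sliced(sid, mask, train_idx),
                                            spec, subject_id=sid,
                                            channel_mask=mask)
            genuine[sid] = cache.sliced(sid, mask, test_idx)
        metrics = evaluate_tar_trr(models, genuine)
    except Exception as exc:
        logger.warning("chromosome evaluation failed (%s); assigning worst "
                       "objectives", exc)
        return (float(len(mask)), 1.0, 1.0)
    return (float(len(mask)), 1.0 - metrics.tar, 1.0 - metrics.trr)


@dataclass
class ParetoRecord:
    run_id: int
    channels: tuple[int, ...]
    n_channels: int
    tar: float
    trr: float
    model: ModelSpec
    genes: tuple[float, ...]
    channel_names: tuple[str, ...] = ()


def run_channel_selection(cohort: Sequence[EEGRecording] | FeatureCache,
                          cfg: ExperimentConfig,
                          log_path: str | None = None) -> list[ParetoRecord]:
    """Repeated-split NSGA-III channel selection; returns all Pareto records.

    Each of ``cfg.n_runs`` runs draws a fresh 80/20 per-subject split (fixed
    for all generations of that run) and evolves an independent population.
    When ``log_path`` is given, per-generation population logs are appended
    as JSON lines.
    """
    if isinstance(cohort, FeatureCache):
        cache = cohort
    else:
        cache = FeatureCache.from_cohort(cohort, cfg.decomposition, cfg.feature,
                                         cfg.window_seconds)
    encoding = make_encoding(cfg.model_family, cache.n_channels)
    channel_names = None
    if not isinstance(cohort, FeatureCache) and len(cohort) > 0:
        channel_names = list(cohort[0].channel_names)

    records: list[ParetoRecord] = []
    log_file = open(log_path, "a") if log_path else None
    try:
        for run_id, run_seed in enumerate(cfg.seeds):
            rng = np.random.default_rng(run_seed)
            splits = split_cohort(cache.instance_counts(), cfg.train_fraction,
                                  rng)

            def fitness(chrom: Chromosome) -> tuple[float, float, float]:
                return evaluate_chromosome(chrom, cache, splits, cfg)

            history: list[dict] = []
            result = evolve(fitness, encoding, n_objectives=3,
                            population_size=cfg.population_size, rng=rng,
                            reference_divisions=cfg.reference_divisions,
                            termination=cfg.run_termination(), log=history)
            if log_file:
                for rec in history:
                    rec = {"run_id": run_id, "seed": run_seed, **rec}
                    log_file.write(json.dumps(rec) + "\n")
            for chrom, objs in zip(result.front, result.front_objectives):
                mask, spec = decode_chromosome(chrom, cfg.model_family,
                                               cfg.lof_accept_threshold)
                records.append(ParetoRecord(
                    run_id=run_id, channels=mask, n_channels=int(objs[0]),
                    tar=1.0 - float(objs[1]), trr=1.0 - float(objs[2]),
                    model=spec, genes=tuple(chrom.genes),
                    channel_names=tuple(channel_names[c] for c in mask)
                    if channel_names else (),
                ))
    finally:
        if log_file:
            log_file.close()
    return records


def records_to_frame(records: Sequence[ParetoRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {"run_id": r.run_id, "n_channels": r.n_channels, "tar": r.tar,
         "trr": r.trr,
         "channels": ";".join(map(str, r.channels)),
         "channel_names": ";".join(r.channel_names),
         "genes": ";".join(f"{g:g}" for g in r.genes)}
        for r in records
    ])


def aggregate_report(records: Sequence[ParetoRecord],
                     max_channels: int | None = None) -> pd.DataFrame:
    """Per-channel-count mean +/- SD of TAR and TRR across runs.

    For each run and channel count, the record with the best TAR + TRR sum is
    taken (runs whose front lacks that channel count contribute nothing);
    means and standard deviations are then computed over runs, mirroring the
    usual "No. channels | TAR +/- SD | TRR +/- SD" presentation.
    """
    if not records:
        raise ValueError("no Pareto records to aggregate")
    frame = records_to_frame(records)
    if max_channels is not None:
        frame = frame[frame.n_channels <= max_channels]
    best = (frame.assign(score=frame.tar + frame.trr)
            .sort_values("score", ascending=False)
            .groupby(["run_id", "n_channels"], as_index=False).first())
    out = best.groupby("n_channels").agg(
        tar_mean=("tar", "mean"), tar_sd=("tar", lambda s: s.std(ddof=0)),
        trr_mean=("trr", "mean"), trr_sd=("trr", lambda s: s.std(ddof=0)),
        n_runs=("run_id", "nunique"),
    ).reset_index()
    return out


def channel_occurrence_map(records: Sequence[ParetoRecord]) -> pd.DataFrame:
    """Counts of each channel's appearances in Pareto records per stratum.

    Rows are (n_channels stratum, channel index, count); counts within a
    stratum sum to the total number of selected channels over that stratum's
    records.
    """
    if not records:
        raise ValueError("no Pareto records")
    counts: dict[tuple[int, int], int] = {}
    names: dict[int, str] = {}
    for rec in records:
        for ch, name in zip(rec.channels,
                            rec.channel_names or [""] * len(rec.channels)):
            counts[(rec.n_channels, ch)] = counts.get((rec.n_channels, ch), 0) + 1
            if name:
                names[ch] = name
    rows = [{"n_channels": k[0], "channel": k[1],
             "channel_name": names.get(k[1], str(k[1])), "count": v}
            for k, v in sorted(counts.items())]
    return pd.DataFrame(rows)
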