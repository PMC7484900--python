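"""Per-subject one-class verification models and TAR/TRR evaluation.

Each enrolled subject gets their own novelty model fitted only on that
subject's genuine training vectors: either a local outlier factor (LOF)
scorer or a one-class SVM with RBF kernel.  At test time the model answers
accept/reject per instance; the cohort metrics are

* TAR (true acceptance rate): fraction of the subject's own test instances
  accepted by the subject's model;
* TRR (true rejection rate): fraction of impostor instances (other subjects'
  test rows) rejected by the model.

Both are averaged unweighted over subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from sklearn.neighbors import LocalOutlierFactor
from sklearn.svm import OneClassSVM

logger = logging.getLogger(__name__)

LOF_ALGORITHM_CODES = {1: "ball_tree", 2: "kd_tree", 3: "brute"}
_GAMMA_EPSILON = 1e-6


@dataclass
class ModelSpec:
    family: str = "lof"                  # "lof" or "ocsvm"
    lof_algorithm: str = "kd_tree"       # "ball_tree" | "kd_tree" | "brute"
    n_neighbors: int = 1                 # 1..10 in the optimizer encoding
    nu: float = 0.5
    gamma: float = 0.1
    lof_accept_threshold: float = 1.5    # accept iff LOF score <= threshold

    def __post_init__(self) -> None:
        if self.family not in ("lof", "ocsvm"):
            raise ValueError(f"unknown model family {self.family!r}")
        if self.family == "lof":
            if self.lof_algorithm not in LOF_ALGORITHM_CODES.values():
                raise ValueError(f"unknown LOF algorithm {self.lof_algorithm!r}")
            if self.n_neighbors < 1:
                raise ValueError("n_neighbors must be >= 1")
        else:
            if not 0 < self.nu <= 1:
                raise ValueError("nu must be in (0, 1]")
            if self.gamma <= 0:
                raise ValueError("gamma must be > 0")


def lof_scores(train: np.ndarray, query: np.ndarray, k: int,
               algorithm: str = "brute") -> np.ndarray:
    """Local outlier factor of each query row against the training set.

    Scores near 1 mean the query sits at the local density of its k training
    neighbors; values well above 1 flag outliers.  The neighbor-search backend
    (``ball_tree``/``kd_tree``/``brute``) is an index structure only and does
    not change the scores.
    """
    train = np.atleast_2d(np.asarray(train, dtype=float))
    query = np.atleast_2d(np.asarray(query, dtype=float))
    if not 1 <= k <= len(train) - 1:
        raise ValueError(f"k must satisfy 1 <= k <= n_train-1, got k={k}, "
                         f"n_train={len(train)}")
    if query.shape[0] == 0:
        return np.zeros(0)
    lof = LocalOutlierFactor(n_neighbors=k, algorithm=algorithm, novelty=True)
    lof.fit(train)
    return -lof.score_samples(query)


@dataclass
class SubjectModel:
    subject_id: str
    spec: ModelSpec
    channel_mask: tuple[int, ...] = ()
    _train: np.ndarray | None = field(default=None, repr=False)
    _estimator: object = field(default=None, repr=False)

    @property
    def n_features(self) -> int:
        return self._train.shape[1]


def fit_subject_model(train: np.ndarray, spec: ModelSpec,
                      subject_id: str = "", channel_mask: tuple[int, ...] = ()
                      ) -> SubjectModel:
    """Fit one subject's novelty model on their genuine training vectors."""
    train = np.atleast_2d(np.asarray(train, dtype=float))
    if train.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    if spec.family == "lof":
        if spec.n_neighbors >= train.shape[0]:
            raise ValueError(
                f"n_neighbors={spec.n_neighbors} must be < n_train={train.shape[0]}"
            )
        est = LocalOutlierFactor(n_neighbors=spec.n_neighbors,
                                 algorithm=spec.lof_algorithm, novelty=True)
        est.fit(train)
    else:
        est = OneClassSVM(kernel="rbf", nu=spec.nu,
                          gamma=max(spec.gamma, _GAMMA_EPSILON))
        est.fit(train)
    return SubjectModel(subject_id=subject_id, spec=spec,
                        channel_mask=tuple(channel_mask),
                        _train=train, _estimator=est)


def score_instances(model: SubjectModel, query: np.ndarray) -> np.ndarray:
    """Binary accept decisions for query rows.

    LOF: accept iff score <= ``lof_accept_threshold``; OC-SVM: accept iff the
    decision function is >= 0.  Boundary ties accept in both families.
    """
    query = np.atleast_2d(np.asarray(query, dtype=float))
    if query.shape[0] == 0:
        return np.zeros(0, dtype=bool)
    if query.shape[1] != model.n_features:
        raise ValueError(f"query dimensionality {query.shape[1]} != "
                         f"training dimensionality {model.n_features}")
    if model.spec.family == "lof":
        scores = -model._estimator.score_samples(query)
        return scores <= model.spec.lof_accept_threshold
    return model._estimator.decision_function(query) >= 0


@dataclass
class BiometricMetrics:
    tar: float
    trr: float
    per_subject: dict[str, tuple[float, float]] = field(default_factory=dict)


def evaluate_tar_trr(models: Mapping[str, SubjectModel],
                     genuine_test: Mapping[str, np.ndarray],
                     impostor_test: Mapping[str, np.ndarray] | None = None
                     ) -> BiometricMetrics:
    """Cohort TAR/TRR with every other subject acting as intruder.

    ``impostor_test`` defaults to, per subject, the concatenated genuine test
    rows of all other subjects.  Subjects without test rows are excluded with
    a warning; overall rates are unweighted means over remaining subjects.
    """
    per_subject: dict[str, tuple[float, float]] = {}
    for sid, model in models.items():
        genuine = np.atleast_2d(np.asarray(genuine_test[sid], dtype=float))
        if impostor_test is not None:
            impostors = np.atleast_2d(np.asarray(impostor_test[sid], dtype=float))
        else:
            others = [np.atleast_2d(np.asarray(genuine_test[o], dtype=float))
                      for o in genuine_test if o != sid]
            impostors = np.vstack(others) if others else np.zeros((0, model.n_features))
        if genuine.shape[0] == 0 or impostors.shape[0] == 0:
            logger.warning("subject %s has no test rows; excluded from TAR/TRR", sid)
            continue
        tar_s = float(np.mean(score_instances(model, genuine)))
        trr_s = float(np.mean(~score_instances(model, impostors)))
        per_subject[sid] = (tar_s, trr_s)
    if not per_subject:
        raise ValueError("no subject had both genuine and impostor test rows")
    tars, trrs = zip(*per_subject.values())
    return BiometricMetrics(tar=float(np.mean(tars)), trr=float(np.mean(trrs)),
                            per_subject=per_subject)


def spec_from_genes(family: str, gene_a: float, gene_b: float,
                    lof_accept_threshold: float = 1.5) -> ModelSpec:
    """Decode the two model genes of a chromosome into a ModelSpec.

    LOF: ``gene_a`` is the integer algorithm code (1 ball tree, 2 k-d tree,
    3 brute force), ``gene_b`` the neighbor count in 1..10.  OC-SVM: the genes
    are decimals in [0, 1] used directly as nu and gamma, repaired away from
    zero.
    """
    if family == "lof":
        code = int(round(gene_a))
        if code not in LOF_ALGORITHM_CODES:
            raise ValueError(f"LOF algorithm gene must be 1, 2 or 3, got {gene_a}")
        k = int(round(gene_b))
        if not 1 <= k <= 10:
            raise ValueError(f"neighbor gene must be in 1..10, got {gene_b}")
        return ModelSpec(family="lof", lof_algorithm=LOF_ALGORITHM_CODES[code],
                         n_neighbors=k, lof_accept_threshold=lof_accept_threshold)
    nu = min(max(float(gene_a), _GAMMA_EPSILON), 1.0)
    gamma = max(float(gene_b), _GAMMA_EPSILON)
    return ModelSpec(family="ocsvm", nu=nu, gamma=gamma)


def default_model_spec(family: str, family_defaults: dict | None = None) -> ModelSpec:
    if family == "lof":
        return ModelSpec(family="lof", lof_algorithm="kd_tree", n_neighbors=1,
                         **(family_defaults or {}))
    return ModelSpec(family="ocsvm", **(family_defaults or {}))
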