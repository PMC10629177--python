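"""End-to-end orchestration: expression matrix in, cluster assignments out.

Variants:

- ``sclstm``      kernel -> pair training -> learned similarity -> clustering
- ``siglstm``     single-branch ablation: cluster the per-cell LSTM embeddings
- ``raw_kernel``  control: cluster the kernel similarity directly
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from sklearn.metrics import silhouette_score

from . import metrics as metrics_mod
from .clustering import (
    agglomerative_from_embedding,
    agglomerative_from_similarity,
    cluster_variants,
    estimate_num_clusters,
    similarity_to_distance,
)
from .io import ClusteringResult, ExpressionMatrix, write_matrix, write_result
from .kernel import KernelMatrix, kernel_embedding
from .siamese import (
    LearnedSimilarity,
    SiameseConfig,
    TrainedPairScorer,
    derive_pseudo_labels,
    embed_single_branch,
    generate_pairs,
    score_all_pairs,
    train_siamese,
)

VARIANTS = ("sclstm", "siglstm", "raw_kernel")
METHODS = ("AG", "KM", "SC")


@dataclass
class RunConfig:
    variant: str = "sclstm"
    method: str = "AG"
    k: int | None = None
    estimate_k: bool = False
    siamese: SiameseConfig = field(default_factory=SiameseConfig)
    use_true_labels_for_pairs: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.k is None and not self.estimate_k:
            self.estimate_k = True
        if self.variant == "siglstm" and self.method == "SC":
            raise ValueError("spectral clustering needs an affinity; "
                             "siglstm produces embeddings (use AG or KM)")

    def config_hash(self) -> str:
        payload = json.dumps(
            {**self.__dict__, "siamese": self.siamese.to_dict()},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    clustering: ClusteringResult
    kernel: KernelMatrix
    similarity: LearnedSimilarity | None = None
    embedding: np.ndarray | None = None
    scorer: TrainedPairScorer | None = None
    metrics: dict | None = None
    log: list[str] = field(default_factory=list)


def _select_repeat(
    S: KernelMatrix, pair_labels: np.ndarray, cfg: RunConfig, k0: int, log: list[str]
) -> TrainedPairScorer:
    """Train n_repeats scorers (seeds seed..seed+r-1) and keep the one whose
    learned similarity clusters with the best *unsupervised* silhouette."""
    best = None
    best_score = -np.inf
    for r in range(cfg.siamese.n_repeats):
        scfg = replace(cfg.siamese, seed=cfg.siamese.seed + r)
        rng = np.random.default_rng(scfg.seed)
        pairs = generate_pairs(pair_labels, scfg, rng)
        scorer = train_siamese(S, pairs, scfg)
        log.append(
            f"repeat {r}: seed={scfg.seed} loss[0]={scorer.epoch_losses[0]:.4f} "
            f"loss[-1]={scorer.epoch_losses[-1]:.4f}"
        )
        if cfg.siamese.n_repeats == 1:
            return scorer
        M = score_all_pairs(scorer, S)
        labels = agglomerative_from_similarity(M, k0).labels
        if len(set(labels.tolist())) < 2:
            score = -np.inf
        else:
            score = silhouette_score(
                similarity_to_distance(M), labels, metric="precomputed"
            )
        log.append(f"repeat {r}: silhouette={score:.4f}")
        if score > best_score:
            best, best_score = scorer, score
    return best


def run_pipeline(
    X: ExpressionMatrix,
    cfg: RunConfig | None = None,
    true_labels=None,
) -> PipelineResult:
    """Execute the full pipeline on an in-memory expression matrix.

    When ``true_labels`` is given it is used for evaluation, and — only if
    ``cfg.use_true_labels_for_pairs`` — for supervised pair construction;
    otherwise training pairs come from pseudo-labels of the kernel matrix.
    """
    cfg = cfg or RunConfig()
    log: list[str] = [f"config_hash={cfg.config_hash()} seed={cfg.seed}"]
    t0 = time.perf_counter()

    S = kernel_embedding(X)
    log.append(f"kernel: n={S.n_cells} [{time.perf_counter() - t0:.2f}s]")

    if cfg.k is not None:
        k0 = cfg.k
        k_source = "given"
    else:
        k0 = estimate_num_clusters(S)
        k_source = "estimated"
        log.append(f"estimated k={k0} from kernel matrix")

    similarity = None
    embedding = None
    scorer = None

    if cfg.variant == "raw_kernel":
        result = cluster_variants(S, k0, cfg.method, seed=cfg.seed)
    else:
        if cfg.use_true_labels_for_pairs:
            if true_labels is None:
                raise ValueError("use_true_labels_for_pairs requires true_labels")
            pair_labels = np.asarray(true_labels)
        else:
            pair_labels = derive_pseudo_labels(S, k0)
        scorer = _select_repeat(S, pair_labels, cfg, k0, log)
        if cfg.variant == "sclstm":
            similarity = score_all_pairs(scorer, S)
            k_final = (
                estimate_num_clusters(similarity) if cfg.estimate_k else k0
            )
            result = cluster_variants(similarity, k_final, cfg.method, seed=cfg.seed)
        else:  # siglstm
            embedding = embed_single_branch(scorer, S)
            if cfg.method == "AG":
                result = agglomerative_from_embedding(embedding, k0)
            else:
                result = cluster_variants(embedding, k0, cfg.method, seed=cfg.seed)
    result.k_source = k_source
    result.seed = cfg.seed
    result.cell_ids = list(X.cell_ids)
    log.append(
        f"clustering: variant={cfg.variant} method={cfg.method} k={result.k} "
        f"[{time.perf_counter() - t0:.2f}s total]"
    )

    scores = None
    if true_labels is not None:
        scores = metrics_mod.evaluate(true_labels, result.labels)
        log.append("metrics: " + json.dumps(scores))

    return PipelineResult(
        clustering=result,
        kernel=S,
        similarity=similarity,
        embedding=embedding,
        scorer=scorer,
        metrics=scores,
        log=log,
    )


def export_embedding(E: np.ndarray, path: str, cell_ids=None) -> None:
    """Write per-cell vectors (one row per cell) for external visualization."""
    E = np.atleast_2d(np.asarray(E, dtype=float))
    ids = cell_ids or [f"cell{i}" for i in range(E.shape[0])]
    with open(path, "w") as fh:
        fh.write("cell_id\t" + "\t".join(f"dim{d}" for d in range(E.shape[1])) + "\n")
        for cid, row in zip(ids, E):
            fh.write(cid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def write_run_artifacts(
    res: PipelineResult, cfg: RunConfig, out_dir: str, force: bool = False
) -> None:
    """labels.tsv, M.csv, metrics.json (if evaluated), run.log, config echo."""
    os.makedirs(out_dir, exist_ok=True)
    targets = ["labels.tsv", "M.csv", "metrics.json", "run.log", "config.echo.yaml"]
    if not force:
        clashes = [t for t in targets if os.path.exists(os.path.join(out_dir, t))]
        if clashes:
            raise FileExistsError(
                f"{clashes} already present in {out_dir!r}; rerun with --force"
            )
    write_result(res.clustering, os.path.join(out_dir, "labels.tsv"))
    M = res.similarity.values if res.similarity is not None else res.kernel.values
    write_matrix(M, os.path.join(out_dir, "M.csv"), res.clustering.cell_ids)
    if res.embedding is not None:
        export_embedding(
            res.embedding, os.path.join(out_dir, "embedding.tsv"),
            res.clustering.cell_ids,
        )
    if res.metrics is not None:
        with open(os.path.join(out_dir, "metrics.json"), "w") as fh:
            json.dump(res.metrics, fh, indent=2)
    with open(os.path.join(out_dir, "run.log"), "w") as fh:
        fh.write("\n".join(res.log) + "\n")
    with open(os.path.join(out_dir, "config.echo.yaml"), "w") as fh:
        yaml.safe_dump(
            {**{k: v for k, v in cfg.__dict__.items() if k != "siamese"},
             "siamese": cfg.siamese.to_dict()},
            fh,
        )
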