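"""End-to-end orchestration: features -> dataset -> CV -> reports.

One :class:`ExperimentConfig` drives a full run: read (or simulate) the
raw inputs, extract per-protein SURF features, assemble a balanced
labelled pair dataset, cross-validate the weighted ELM, and write
metrics tables, ROC points, per-fold model archives and a manifest.  A
single global seed deterministically derives per-stage seeds, so stages
can be reproduced in isolation and two runs with the same config are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dataio, evaluation, surf, synthetic, welm

logger = logging.getLogger(__name__)


def derive_seed(master: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 derived from the global seed."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment.

    Exactly one input mode: either the three file paths, or
    ``synthetic`` settings (a preset name or a settings mapping).
    """

    pssm_dir: str | None = None
    fingerprint_table: str | None = None
    interaction_table: str | None = None
    synthetic: str | dict | None = "separable"
    surf: surf.SurfConfig = field(default_factory=surf.SurfConfig)
    model: welm.WELMConfig = field(default_factory=welm.WELMConfig)
    cv_folds: int = 5
    negative_ratio: float = 1.0
    baseline: bool = False
    out_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        file_mode = self.pssm_dir is not None
        if file_mode == (self.synthetic is not None):
            raise ValueError(
                "configure exactly one input mode: file paths or synthetic settings"
            )
        if file_mode and not (self.fingerprint_table and self.interaction_table):
            raise ValueError("file mode needs pssm_dir, fingerprint_table and "
                             "interaction_table")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "surf" in raw:
            raw["surf"] = surf.SurfConfig(**raw["surf"])
        if "model" in raw:
            model = dict(raw["model"])
            if model.get("scale_cols") is not None:
                model["scale_cols"] = tuple(model["scale_cols"])
            raw["model"] = welm.WELMConfig(**model)
        return cls(**raw)

    def resolve_synthetic(self) -> synthetic.SyntheticSettings | None:
        if self.synthetic is None:
            return None
        if isinstance(self.synthetic, str):
            settings = synthetic.PRESETS[self.synthetic]
        else:
            settings = synthetic.SyntheticSettings(**self.synthetic)
        return replace(settings, seed=derive_seed(self.seed, "synthetic"))


@dataclass
class ExperimentResult:
    report: evaluation.MetricsReport
    baseline_report: evaluation.MetricsReport | None
    manifest: dict
    out_dir: Path


# ---------------------------------------------------------------------------
# feature cache
# ---------------------------------------------------------------------------


class FeatureCache:
    """On-disk memo of protein features keyed by (PSSM, surf-config) hash."""

    def __init__(self, path) -> None:
        self.path = Path(path)
        self._store = {}
        if self.path.exists():
            with np.load(self.path) as npz:
                self._store = {k: npz[k] for k in npz.files}

    @staticmethod
    def key(pssm: dataio.PSSM, config: surf.SurfConfig) -> str:
        h = hashlib.sha256()
        h.update(pssm.scores.tobytes())
        h.update(repr(config).encode())
        return h.hexdigest()

    def get(self, key: str):
        return self._store.get(key)

    def put(self, key: str, vector: np.ndarray) -> None:
        self._store[key] = np.asarray(vector)

    def save(self) -> None:
        self.path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(self.path, **self._store)


def extract_all_features(
    pssms: dict, config: surf.SurfConfig, cache: FeatureCache | None = None
) -> dict:
    """Per-protein feature vectors, via the cache where possible.

    Bag-of-visual-words pooling needs a codebook shared across proteins
    and therefore bypasses the per-protein cache.
    """
    if config.pooling == "bovw" or cache is None:
        feats = surf.extract_features_batch(pssms, config)
        return {pid: f.vector for pid, f in feats.items()}
    out = {}
    for pid, pssm in pssms.items():
        key = FeatureCache.key(pssm, config)
        vec = cache.get(key)
        if vec is None:
            vec = surf.extract_protein_features(pssm, config).vector
            cache.put(key, vec)
        out[pid] = vec
    return out


# ---------------------------------------------------------------------------
# experiment driver
# ---------------------------------------------------------------------------


def load_inputs(config: ExperimentConfig):
    """Read or simulate (net, pssms, fingerprints) per the config."""
    settings = config.resolve_synthetic()
    if settings is not None:
        logger.info("simulating synthetic world: %s", settings)
        net, _world, pssms, fingerprints = synthetic.simulate_world(settings)
        return net, pssms, fingerprints
    logger.info("reading inputs from %s", config.pssm_dir)
    pssms = dataio.read_pssm_dir(config.pssm_dir)
    fingerprints = dataio.read_fingerprints(config.fingerprint_table)
    net = dataio.read_interactions(
        config.interaction_table, drugs=fingerprints.keys(), targets=pssms.keys()
    )
    return net, pssms, fingerprints


def build_dataset(config: ExperimentConfig, cache: FeatureCache | None = None):
    """Features + balanced negatives -> labelled pair samples."""
    net, pssms, fingerprints = load_inputs(config)
    features = extract_all_features(pssms, config.surf, cache)
    n_neg = int(round(config.negative_ratio * net.n_positive))
    negatives = dataio.sample_negatives(
        net, n=n_neg, seed=derive_seed(config.seed, "negatives")
    )
    samples = dataio.assemble_dataset(net, negatives, features, fingerprints)
    protein_dim = len(next(iter(features.values())))
    return samples, net, protein_dim


def _scaled_model_config(config: ExperimentConfig, protein_dim: int) -> welm.WELMConfig:
    # z-score the protein block with training-fold statistics; leave the
    # trailing fingerprint bits untouched
    return replace(
        config.model,
        scale_cols=tuple(range(protein_dim)),
        seed=derive_seed(config.seed, "hidden"),
    )


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Execute the whole protocol and write the report bundle.

    Outputs under ``config.out_dir``: ``welm_metrics.tsv`` (per-fold
    table plus mean +/- sd), ``roc_fold<k>.tsv`` ROC points,
    ``model_fold<k>.npz`` archives for models refit per fold, an
    ``elm_metrics.tsv`` baseline table when ``baseline`` is set, and
    ``manifest.json`` with config, derived seeds and sample counts.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cache = FeatureCache(out_dir / "feature_cache.npz")
    samples, net, protein_dim = build_dataset(config, cache)
    cache.save()
    model_config = _scaled_model_config(config, protein_dim)
    cv_seed = derive_seed(config.seed, "folds")

    report, roc_points = evaluation.kfold_cross_validate(
        samples, model_config, k=config.cv_folds, seed=cv_seed
    )
    report.write_tsv(out_dir / "welm_metrics.tsv")
    for fold, curve in roc_points.items():
        pd.DataFrame(curve, columns=["fpr", "tpr"]).to_csv(
            out_dir / f"roc_fold{fold}.tsv", sep="\t", index=False, float_format="%.6f"
        )

    baseline_report = None
    if config.baseline:
        elm_config = replace(model_config, strategy="none")
        baseline_report, _ = evaluation.kfold_cross_validate(
            samples, elm_config, k=config.cv_folds, seed=cv_seed
        )
        baseline_report.write_tsv(out_dir / "elm_metrics.tsv")

    # one refit per fold's training share is what CV evaluated; archive a
    # single full-data model for downstream use instead
    X, y = dataio.dataset_arrays(samples)
    welm.save_model(welm.fit(X, y, model_config), out_dir / "model_full.npz")

    n_pos = sum(1 for s in samples if s.label == dataio.POSITIVE)
    manifest = {
        "config": _jsonable(config),
        "seeds": {
            stage: derive_seed(config.seed, stage)
            for stage in ("synthetic", "negatives", "hidden", "folds")
        },
        "n_drugs": len(net.drugs),
        "n_targets": len(net.targets),
        "n_positive": n_pos,
        "n_negative": len(samples) - n_pos,
        "protein_feature_dim": protein_dim,
        "feature_dim": protein_dim + dataio.FINGERPRINT_BITS,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return ExperimentResult(report, baseline_report, manifest, out_dir)


def _jsonable(config: ExperimentConfig) -> dict:
    d = asdict(config)
    if d.get("model", {}).get("scale_cols") is not None:
        d["model"]["scale_cols"] = list(d["model"]["scale_cols"])
    return d


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------


def grid_search(
    dataset,
    base_config: welm.WELMConfig,
    n_hidden_grid,
    C_grid,
    k: int = 5,
    seed: int = 0,
):
    """Exhaustive (n_hidden, C) search scored by CV mean accuracy.

    Deterministic: ties resolve to the first grid point in iteration
    order (n_hidden-major).  Returns the winning config and the full
    score table.
    """
    n_hidden_grid = list(n_hidden_grid)
    C_grid = list(C_grid)
    if not n_hidden_grid or not C_grid:
        raise ValueError("grid search needs a non-empty grid")
    rows = []
    best = None
    for n_hidden in n_hidden_grid:
        for C in C_grid:
            candidate = replace(base_config, n_hidden=n_hidden, C=C)
            report, _ = evaluation.kfold_cross_validate(dataset, candidate, k=k, seed=seed)
            score = report.mean("acc")
            rows.append({"n_hidden": n_hidden, "C": C, "mean_acc": score})
            if best is None or score > best[0]:
                best = (score, candidate)
    table = pd.DataFrame(rows)
    return best[1], table
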