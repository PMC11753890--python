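"""End-to-end orchestration: feature extraction, integration, selection,
training and prediction.

The train-time and predict-time paths share the same transform code,
parameterized by stored state (normalization statistics, learned view
weights, selected-feature mask, classifier parameters), so nothing fitted on
training data is ever re-estimated at prediction time.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from targetclp.btg_selection import BTGSelector, FeatureMask, apply_mask
from targetclp.clbp_transform import pssm_clbp, recm_clbp
from targetclp.de_integration import DEWeightIntegrator, weighted_concat
from targetclp.embeddings import load_precomputed, mean_pool, mock_embed
from targetclp.io_formats import (
    EnergyContactMatrix,
    FeatureTable,
    FormatError,
    ModelBundle,
    ProfileMatrix,
    ProteinRecord,
    read_energy_matrix,
    read_fasta,
    read_pssm_ascii,
)
from targetclp.qlc_features import QLC_DIM, QLCNormalizer, qlc_vector
from targetclp.snbilstm_classifier import SnBiLSTMClassifier

ALL_VIEWS = ("ESM", "PSSM-CLBP", "QLC", "RECM-CLBP")


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    fasta: str | None = None
    pssm_dir: str | None = None
    recm: str | None = None
    embeddings_dir: str | None = None  # precomputed per-sequence matrices
    labels: str | None = None
    views: tuple = ALL_VIEWS
    embed_dim: int = 1280
    de: dict = field(default_factory=dict)       # DEWeightIntegrator overrides
    btg: dict = field(default_factory=dict)      # BTGSelector overrides
    classifier: dict = field(default_factory=dict)  # SnBiLSTMClassifier overrides
    k: int = 5
    threshold: float = 0.5
    seed: int = 0
    output_dir: str = "targetclp_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.views = tuple(cfg.views)
        return cfg

    def to_dict(self) -> dict:
        out = asdict(self)
        out["views"] = list(self.views)
        return out


def extract_features(
    records: list[ProteinRecord],
    config: PipelineConfig,
    pssms: dict[str, ProfileMatrix] | None = None,
    ecm: EnergyContactMatrix | None = None,
    labels: np.ndarray | None = None,
) -> FeatureTable:
    """Build the multi-view feature table for a set of records.

    Per sequence the enabled views are computed in fixed order (ESM 1280,
    PSSM-CLBP 236, QLC 147, RECM-CLBP 236; full set width 1899).  Records
    missing a required PSSM or precomputed embedding raise an error listing
    the offending ids.
    """
    views = [v for v in ALL_VIEWS if v in config.views]
    if not views:
        raise ValueError("no feature views enabled")
    if "PSSM-CLBP" in views and pssms is not None:
        missing = [r.id for r in records if r.id not in pssms]
        if missing:
            raise FileNotFoundError(f"missing PSSM for records: {missing}")
    rows, dims = [], None
    for rec in records:
        parts = []
        for view in views:
            if view == "ESM":
                if config.embeddings_dir:
                    emb = load_precomputed(
                        Path(config.embeddings_dir) / f"{rec.id}.npy",
                        expected_length=len(rec.sequence),
                    )
                else:
                    emb = mock_embed(rec, dim=config.embed_dim, seed=config.seed)
                parts.append(mean_pool(emb))
            elif view == "PSSM-CLBP":
                if pssms is None:
                    raise FileNotFoundError("PSSM-CLBP view enabled but no PSSMs given")
                parts.append(pssm_clbp(pssms[rec.id]).vector)
            elif view == "QLC":
                parts.append(qlc_vector(rec))
            else:  # RECM-CLBP
                if ecm is None:
                    raise FileNotFoundError("RECM-CLBP view enabled but no energy matrix given")
                parts.append(recm_clbp(rec, ecm).vector)
        if dims is None:
            dims = [len(p) for p in parts]
        rows.append(np.concatenate(parts))
    return FeatureTable(
        ids=[r.id for r in records],
        block_names=views,
        block_dims=dims,
        matrix=np.vstack(rows),
        labels=labels,
    )


def load_inputs(config: PipelineConfig):
    """Read FASTA, PSSM files (<id>.pssm in pssm_dir), energy matrix and
    labels (TSV: id <tab> 0/1) as configured."""
    records = read_fasta(config.fasta)
    pssms = None
    if "PSSM-CLBP" in config.views:
        if not config.pssm_dir:
            raise FileNotFoundError("PSSM-CLBP view enabled but pssm_dir not set")
        pssms = {}
        for rec in records:
            path = Path(config.pssm_dir) / f"{rec.id}.pssm"
            if not path.exists():
                raise FileNotFoundError(f"missing PSSM file {path}")
            pssms[rec.id] = read_pssm_ascii(path, sequence=rec.sequence)
    ecm = None
    if "RECM-CLBP" in config.views:
        if not config.recm:
            raise FileNotFoundError("RECM-CLBP view enabled but recm path not set")
        ecm = read_energy_matrix(config.recm)
    labels = None
    if config.labels:
        table = {}
        for line in Path(config.labels).read_text().splitlines():
            if line.strip():
                rid, val = line.split("\t")
                table[rid] = int(val)
        labels = np.array([table[r.id] for r in records])
    return records, pssms, ecm, labels


class TargetCLPModel:
    """The fitted pipeline: QLC normalization, DE view weights, BTG feature
    mask, and the SnBiLSTM classifier, with ModelBundle persistence."""

    def __init__(self, config: PipelineConfig | None = None):
        self.config = config or PipelineConfig()

    # -- training ----------------------------------------------------------

    def fit(self, table: FeatureTable) -> "TargetCLPModel":
        if table.labels is None:
            raise ValueError("training requires labels")
        cfg = self.config
        table = self._normalize_qlc(table, fit=True)

        integ = DEWeightIntegrator(
            block_dims=list(table.block_dims),
            seed=cfg.seed,
            cv=cfg.k,
            **cfg.de,
        )
        integ.fit(table.matrix, table.labels)
        self.weights_ = integ.weights_
        self.de_trace_ = integ.result_.trace
        weighted = weighted_concat(table, self.weights_)

        selector = BTGSelector(seed=cfg.seed, cv=cfg.k, **cfg.btg)
        selector.fit(weighted, table.labels)
        self.mask_ = selector.support_
        self.btg_trace_ = selector.trace_

        clf = SnBiLSTMClassifier(
            seed=cfg.seed, threshold=cfg.threshold, **cfg.classifier
        )
        clf.fit(weighted[:, self.mask_], table.labels)
        self.classifier_ = clf
        self.block_dims_ = list(table.block_dims)
        self.block_names_ = list(table.block_names)
        return self

    # -- prediction --------------------------------------------------------

    def predict(self, table: FeatureTable, threshold: float | None = None):
        """Apply stored transforms; returns (probabilities, labels)."""
        if list(table.block_names) != self.block_names_:
            raise FormatError(
                f"feature blocks {table.block_names} do not match the "
                f"trained model's {self.block_names_}"
            )
        table = self._normalize_qlc(table, fit=False)
        weighted = weighted_concat(table, self.weights_)
        probs = self.classifier_.predict_proba(weighted[:, self.mask_])[:, 1]
        th = self.config.threshold if threshold is None else threshold
        return probs, (probs > th).astype(int)

    def _normalize_qlc(self, table: FeatureTable, fit: bool) -> FeatureTable:
        if "QLC" not in table.block_names:
            if fit:
                self.qlc_normalizer_ = None
            return table
        sl = table.block_slices()["QLC"]
        matrix = table.matrix.copy()
        if fit:
            self.qlc_normalizer_ = QLCNormalizer().fit(matrix[:, sl])
        elif getattr(self, "qlc_normalizer_", None) is None:
            raise ValueError("model has no fitted QLC normalization statistics")
        matrix[:, sl] = self.qlc_normalizer_.transform(matrix[:, sl])
        return FeatureTable(table.ids, list(table.block_names),
                            list(table.block_dims), matrix, table.labels)

    # -- persistence -------------------------------------------------------

    def to_bundle(self) -> ModelBundle:
        from targetclp import __version__

        clf = self.classifier_
        config = {
            "package_version": __version__,
            "pipeline": self.config.to_dict(),
            "block_names": self.block_names_,
            "block_dims": self.block_dims_,
            "classifier": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in clf.get_params().items()},
            "n_selected": int(self.mask_.sum()),
        }
        norm = getattr(self, "qlc_normalizer_", None)
        return ModelBundle(
            qlc_mean=None if norm is None else norm.mean_,
            qlc_std=None if norm is None else norm.scale_,
            weights=self.weights_,
            mask=self.mask_,
            classifier_params=clf.export_params(),
            config=config,
        )

    def save(self, directory) -> None:
        self.to_bundle().save(directory)

    @classmethod
    def load(cls, directory) -> "TargetCLPModel":
        bundle = ModelBundle.load(directory)
        cfg = PipelineConfig(**bundle.config["pipeline"])
        cfg.views = tuple(cfg.views)
        model = cls(cfg)
        model.block_names_ = list(bundle.config["block_names"])
        model.block_dims_ = [int(d) for d in bundle.config["block_dims"]]
        model.weights_ = np.asarray(bundle.weights)
        model.mask_ = np.asarray(bundle.mask, dtype=bool)
        if bundle.qlc_mean is not None:
            norm = QLCNormalizer()
            norm.mean_ = np.asarray(bundle.qlc_mean)
            norm.scale_ = np.asarray(bundle.qlc_std)
            norm.constant_mask_ = norm.scale_ == 1.0
            norm.n_features_in_ = len(norm.mean_)
            model.qlc_normalizer_ = norm
        else:
            model.qlc_normalizer_ = None
        clf_params = dict(bundle.config["classifier"])
        if isinstance(clf_params.get("dense_sizes"), list):
            clf_params["dense_sizes"] = tuple(clf_params["dense_sizes"])
        clf = SnBiLSTMClassifier(**clf_params)
        clf.import_params(bundle.classifier_params, n_features=int(bundle.mask.sum()))
        model.classifier_ = clf
        return model


def fit_pipeline(config: PipelineConfig) -> TargetCLPModel:
    """Load inputs per config, extract features, fit, persist, return model."""
    records, pssms, ecm, labels = load_inputs(config)
    if labels is None:
        raise ValueError("fit_pipeline requires a labels file")
    table = extract_features(records, config, pssms=pssms, ecm=ecm, labels=labels)
    model = TargetCLPModel(config).fit(table)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    model.save(out / "bundle")
    manifest = {"config": config.to_dict(),
                "weights": [float(w) for w in model.weights_],
                "n_selected": int(model.mask_.sum())}
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return model


def predict_pipeline(model: TargetCLPModel, config: PipelineConfig):
    """Extract features for new records and predict with the stored model."""
    records, pssms, ecm, _ = load_inputs(config)
    table = extract_features(records, config, pssms=pssms, ecm=ecm)
    probs, labels = model.predict(table, threshold=config.threshold)
    return [r.id for r in records], probs, labels
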