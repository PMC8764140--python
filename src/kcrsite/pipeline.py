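"""End-to-end orchestration: split, undersample, encode, select, train, score.

Execution order enforces the leakage-free protocol: the 80/20 stratified split
happens first on the raw site list; undersampling and feature selection are
fitted on the training side only; the imbalanced test side is touched exactly
once, to score the final model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .contact_features import DEFAULT_CONTACT_THRESHOLD, filter_contacts
from .evaluation import EvalReport, evaluate_predictions
from .feature_selection import SelectionResult, chi_square_select, information_gain_select
from .io_formats import (
    read_contact_table,
    read_fasta,
    read_pssm,
    read_site_labels,
    write_feature_matrix,
)
from .modeling import (
    ModelSpec,
    TrainedModel,
    grid_search_train,
    predict_scores,
    train_test_split,
    undersample_balance,
)
from .sequence_encoders import Sample, build_matrix

logger = logging.getLogger(__name__)

_CLASSIFIER_ALIASES = {
    "svm": "svm_rbf", "svm_rbf": "svm_rbf",
    "rf": "random_forest", "random_forest": "random_forest",
    "lr": "logistic_regression", "logistic_regression": "logistic_regression",
}


@dataclass
class RunConfig:
    """Everything one pipeline run needs; all seeds are explicit."""

    fasta: str
    sites: str
    contacts_dir: str | None = None
    pssm_dir: str | None = None
    out_dir: str = "run_out"
    half_width: int = 10
    encoders: tuple[str, ...] = ("rrpc",)
    contact_threshold: float = DEFAULT_CONTACT_THRESHOLD
    cksaap_gaps: tuple[int, ...] = (1, 2, 3)
    subwindow: int = 5
    selection: str = "none"  # none | chi2 | ig
    alpha: float = 0.05
    ig_bins: int = 2
    top_k: int | None = None
    classifier: str = "rf"
    grid: dict = field(default_factory=dict)
    objective: str = "auc"
    cutoff: float = 0.5
    split_fraction: float = 0.8
    cv: int = 5
    seed_split: int = 0
    seed_undersample: int = 1
    seed_model: int = 2
    write_matrices: bool = True

    def __post_init__(self) -> None:
        if isinstance(self.encoders, str):
            self.encoders = tuple(e.strip() for e in self.encoders.split(",") if e.strip())
        else:
            self.encoders = tuple(self.encoders)
        self.cksaap_gaps = tuple(self.cksaap_gaps)
        if self.classifier not in _CLASSIFIER_ALIASES:
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.selection not in ("none", "chi2", "ig"):
            raise ValueError(f"unknown selection method {self.selection!r}")
        if self.half_width < 1:
            raise ValueError("half_width must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["encoders"] = list(self.encoders)
        payload["cksaap_gaps"] = list(self.cksaap_gaps)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def load_samples(config: RunConfig) -> list[Sample]:
    """Read inputs and assemble one Sample per labeled site."""
    proteins = read_fasta(config.fasta)
    by_id = {p.id: p for p in proteins}
    labels = read_site_labels(config.sites, proteins)
    needs_contacts = any(e in ("rrc", "rrpc") for e in config.encoders)
    needs_pssm = "pssm" in config.encoders
    cmaps = {}
    if needs_contacts:
        if config.contacts_dir is None:
            raise ValueError("encoders rrc/rrpc require contacts_dir")
        for pid, protein in by_id.items():
            path = Path(config.contacts_dir) / f"{pid}.contacts"
            if not path.exists():
                raise FileNotFoundError(f"no contact table for protein {pid!r}: {path}")
            cmap = read_contact_table(path, protein_id=pid)
            cmap.validate_for(protein)
            cmaps[pid] = filter_contacts(cmap, config.contact_threshold)
    pssms = {}
    if needs_pssm:
        if config.pssm_dir is None:
            raise ValueError("encoder pssm requires pssm_dir")
        for pid, protein in by_id.items():
            path = Path(config.pssm_dir) / f"{pid}.pssm"
            if not path.exists():
                raise FileNotFoundError(f"no PSSM for protein {pid!r}: {path}")
            pssms[pid] = read_pssm(path, protein=protein)
    return [
        Sample(
            protein=by_id[lab.protein_id],
            site=lab,
            contact_map=cmaps.get(lab.protein_id),
            pssm=pssms.get(lab.protein_id),
        )
        for lab in labels
    ]


def run_pipeline(config: RunConfig) -> EvalReport:
    """Run the full protocol and write every intermediate under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"kcrsite {__version__}"]

    def stage(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    try:
        samples = load_samples(config)
    except Exception as exc:
        raise RuntimeError(f"stage load: {exc}") from exc
    n_pos = sum(1 for s in samples if s.label == "positive")
    stage(f"load: {len(samples)} sites ({n_pos} positive, {len(samples) - n_pos} negative)")

    train_samples, test_samples = train_test_split(
        samples, fraction=config.split_fraction, seed=config.seed_split
    )
    stage(f"split: {len(train_samples)} train / {len(test_samples)} test (stratified)")

    def encode(subset, tag):
        try:
            return build_matrix(
                list(config.encoders), subset,
                half_width=config.half_width,
                cksaap_gaps=config.cksaap_gaps,
                subwindow=config.subwindow,
            )
        except Exception as exc:
            raise RuntimeError(f"stage encode[{tag}]: {exc}") from exc

    train_matrix = encode(train_samples, "train")
    test_matrix = encode(test_samples, "test")
    stage(f"encode: {train_matrix.n_features} dimensions ({','.join(config.encoders)})")

    try:
        train_matrix = undersample_balance(train_matrix, seed=config.seed_undersample)
    except Exception as exc:
        raise RuntimeError(f"stage undersample: {exc}") from exc
    stage(f"undersample: train balanced to {train_matrix.n_samples} samples (1:1)")

    selection: SelectionResult | None = None
    if config.selection != "none":
        try:
            if config.selection == "chi2":
                selection = chi_square_select(train_matrix, alpha=config.alpha)
            else:
                selection = information_gain_select(
                    train_matrix, bins=config.ig_bins, top_k=config.top_k
                )
        except Exception as exc:
            raise RuntimeError(f"stage select: {exc}") from exc
        train_matrix = selection.apply(train_matrix)
        test_matrix = selection.apply(test_matrix)
        stage(f"select[{config.selection}]: kept {selection.n_kept} dimensions")

    spec = ModelSpec(
        kind=_CLASSIFIER_ALIASES[config.classifier],
        grid={k: tuple(v) for k, v in config.grid.items()},
        cutoff=config.cutoff,
        seed=config.seed_model,
        objective=config.objective,
    )
    try:
        model = grid_search_train(train_matrix, spec, k=config.cv)
    except Exception as exc:
        raise RuntimeError(f"stage train: {exc}") from exc
    stage(f"train[{spec.kind}]: chose {model.chosen} by {config.cv}-fold CV {config.objective}")

    try:
        scores = predict_scores(model, test_matrix)
        report = evaluate_predictions(scores, test_matrix.labels, cutoff=config.cutoff)
    except Exception as exc:
        raise RuntimeError(f"stage evaluate: {exc}") from exc
    stage(
        f"evaluate: Acc={report.Acc:.4f} AUC={report.AUC:.4f} MCC={report.MCC:.4f} "
        f"on {test_matrix.n_samples} imbalanced test sites"
    )

    # artifacts
    config.to_yaml(out / "config.yaml")
    if config.write_matrices:
        write_feature_matrix(train_matrix, out / "train_matrix.csv")
        write_feature_matrix(test_matrix, out / "test_matrix.csv")
    if selection is not None:
        selection.to_json(out / "selection.json")
    model.save(out / "model.joblib")
    report.to_json(out / "report.json")
    report.to_csv(out / "report.csv")
    scores_payload = {
        sid: float(s) for sid, s in zip(test_matrix.sample_ids, scores)
    }
    (out / "test_scores.json").write_text(json.dumps(scores_payload, sort_keys=True))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return report
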