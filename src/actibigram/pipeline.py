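"""End-to-end pipeline: preprocess -> features -> associate, with manifest.

The pipeline reads a long-format counts CSV and a phenotype CSV, applies
non-wear detection and participant validation, computes the per-participant
feature table, fits the requested swap-model grid, and writes four
artifacts into the output directory:

    validity_report.tsv    one row per participant with pass/fail reasons
    state_sequences.csv    masked S/L/M/V/'.' sequences of valid participants
    features.tsv           the feature table (bigrams, u-bigrams, durations)
    associations.tsv       one row per (baseline, comparison, model) contrast
    manifest.json          config echo, config hash, and library versions

Outputs are deterministic functions of the inputs and configuration, so a
re-run with the same config is byte-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .features import cohort_features
from .io import (
    read_counts_csv,
    read_phenotypes_csv,
    write_association_results,
    write_feature_table,
    write_state_sequences,
    write_validity_report,
)
from .models import run_full_grid
from .preprocess import (
    CutPoints,
    ValidityRules,
    categorize,
    detect_nonwear,
    validate_participant,
)

logger = logging.getLogger("actibigram")


class EmptyCohortError(ValueError):
    """Raised when validation leaves no analyzable participants."""


@dataclass
class PipelineConfig:
    """Paths, filtering rules and model-grid requests for one run."""

    counts_csv: str
    output_dir: str
    phenotype_csv: str | None = None
    n_days: int = 7
    epochs_per_day: int = 1440
    pad_partial: bool = False
    cut_points: CutPoints = field(default_factory=CutPoints)
    validity_rules: ValidityRules = field(default_factory=ValidityRules)
    day_policy: str = "all_days"  # or "valid_days_only" (sensitivity mode)
    outcome: str = "BMI"
    covariates: tuple[str, ...] = ()
    kinds: tuple[str, ...] = ("state_transfer", "ubigram_swap")
    adjustments: tuple[str, ...] = ("model1", "model2")
    scale: str = "per_10"
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cut_points"] = dataclasses.asdict(self.cut_points)
        d["validity_rules"] = dataclasses.asdict(self.validity_rules)
        return d


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from YAML or JSON."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        raw = json.loads(text)
    else:
        import yaml

        raw = yaml.safe_load(text)
    raw = dict(raw)
    if "cut_points" in raw:
        raw["cut_points"] = CutPoints(**raw["cut_points"])
    if "validity_rules" in raw:
        raw["validity_rules"] = ValidityRules(**raw["validity_rules"])
    for key in ("covariates", "kinds", "adjustments"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)


def config_hash(config: PipelineConfig) -> str:
    canon = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the manifest dict it wrote."""
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    cohort = read_counts_csv(
        config.counts_csv,
        n_days=config.n_days,
        epochs_per_day=config.epochs_per_day,
        pad_partial=config.pad_partial,
    )
    logger.info("read %d participants from %s", len(cohort), config.counts_csv)

    masked = [detect_nonwear(s, config.validity_rules) for s in cohort]
    reports = [validate_participant(s, config.validity_rules) for s in masked]
    write_validity_report(reports, out_dir / "validity_report.tsv")
    valid_ids = {r.participant_id for r in reports if r.valid}
    valid_raw = [s for s in cohort if s.participant_id in valid_ids]
    logger.info("%d of %d participants valid", len(valid_raw), len(cohort))
    if not valid_raw:
        raise EmptyCohortError("no participant passed the validity rules")

    seqs = [
        categorize(s, config.cut_points)
        for s in masked
        if s.participant_id in valid_ids
    ]
    write_state_sequences(seqs, out_dir / "state_sequences.csv")

    features = cohort_features(
        valid_raw, config.cut_points, config.validity_rules, config.day_policy
    )
    write_feature_table(features, out_dir / "features.tsv")

    n_contrasts = 0
    if config.phenotype_csv is not None:
        pheno = read_phenotypes_csv(config.phenotype_csv)
        table = features.merge(
            pheno[
                ["participant_id", config.outcome]
                + [c for c in config.covariates if c in pheno.columns]
            ],
            on="participant_id",
            how="inner",
        )
        results = run_full_grid(
            table,
            kinds=config.kinds,
            adjustments=config.adjustments,
            scale=config.scale,
            covariates=config.covariates,
            outcome=config.outcome,
            nd=config.epochs_per_day,
        )
        write_association_results(results, out_dir / "associations.tsv")
        n_contrasts = len(results)

    manifest = {
        "actibigram_version": __version__,
        "config": config.to_dict(),
        "config_sha256": config_hash(config),
        "seed": config.seed,
        "day_policy": config.day_policy,
        "n_participants_read": len(cohort),
        "n_participants_valid": len(valid_raw),
        "n_contrasts": n_contrasts,
        "library_versions": _library_versions(),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _library_versions() -> dict[str, str]:
    import numpy
    import pandas
    import statsmodels

    return {
        "numpy": numpy.__version__,
        "pandas": pandas.__version__,
        "statsmodels": statsmodels.__version__,
    }
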