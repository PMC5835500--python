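"""End-to-end pipeline: assemble -> encode -> prefer -> mine -> validate.

One configuration drives the whole analysis and produces a reproducible
result bundle: cleaning report, preference tables and rule sets for the
four datasets (raw/encoded alphabet x N+/N- class), optional conformity
and motif-validation reports, a summary table, and a manifest hashing
inputs and outputs so reruns can be verified bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from importlib.metadata import version as _pkg_version
from pathlib import Path

import pandas as pd
import yaml

from . import dataset as ds
from .encoding import GroupEncoder, build_default_scheme
from .mining import AssociationRuleMiner, rules_to_table, write_rules_json
from .validation import (
    conformity_report,
    load_motif_table,
    read_prediction_tsv,
    validate_motif_table,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    fasta: str
    sites: str
    out_dir: str
    flank: int = 10
    ratio: str = "1:1"
    seed: int = 42
    alpha: float = 0.05
    correction: str = "none"
    support_grid: tuple[float, ...] = tuple(range(5, 100, 5))
    maximal_only: bool = True
    predictions: str | None = None  # optional predictor-output TSV
    motifs: str | None = None  # optional literature motif TSV

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "support_grid" in data:
            data["support_grid"] = tuple(data["support_grid"])
        return cls(**data)

    def check(self) -> None:
        for p in (self.fasta, self.sites, self.predictions, self.motifs):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        out = Path(self.out_dir).resolve()
        for p in (self.fasta, self.sites):
            if Path(p).resolve().parent == out:
                raise ValueError("outputs must not overwrite inputs")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
                raise PipelineError(name, exc) from exc
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the result bundle; returns the summary."""
    config.check()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- assemble ---------------------------------------------------------
    @_stage("assemble")
    def assemble():
        proteins, sites = ds.parse_inputs(config.fasta, config.sites)
        proteins, sites, report = ds.clean_dataset(proteins, sites)
        positives = [s for s in sites if s.label == ds.POSITIVE]
        if not positives:
            raise ValueError("no positive sites after cleaning")
        negatives = ds.enumerate_negative_sites(proteins, positives)
        balanced = ds.balance_dataset(
            positives, negatives, ratio=config.ratio, seed=config.seed
        )
        return proteins, positives, negatives, balanced, report

    proteins, positives, negatives, balanced, report = assemble()
    (out / "cleaning_report.json").write_text(
        json.dumps(report.to_dict(), indent=2) + "\n"
    )
    logger.info(
        "assembled %d proteins, %d positive / %d negative sites (%d balanced)",
        len(proteins), len(positives), len(negatives), len(balanced),
    )

    # -- windows + encoding ----------------------------------------------
    @_stage("encode")
    def encode():
        pos_w = ds.extract_windows(proteins, positives, flank=config.flank)
        neg_w = ds.extract_windows(proteins, balanced, flank=config.flank)
        encoder = GroupEncoder().fit(pos_w)
        return pos_w, neg_w, encoder.transform(pos_w), encoder.transform(neg_w)

    pos_raw, neg_raw, pos_enc, neg_enc = encode()
    raw_pos_strings = [w.symbols for w in pos_raw]
    raw_neg_strings = [w.symbols for w in neg_raw]

    # -- preference + mining on the four datasets -------------------------
    datasets = {
        ("raw", "N+"): (raw_pos_strings, raw_neg_strings, "positive"),
        ("raw", "N-"): (raw_neg_strings, raw_pos_strings, "negative"),
        ("encoded", "N+"): (pos_enc, neg_enc, "positive"),
        ("encoded", "N-"): (neg_enc, pos_enc, "negative"),
    }
    summary_rows = {}
    miners = {}
    for (alphabet, label), (cls_w, other_w, consequent) in datasets.items():
        @_stage(f"mine[{alphabet},{label}]")
        def mine(cls_w=cls_w, other_w=other_w, consequent=consequent, label=label):
            miner = AssociationRuleMiner(
                support_grid=config.support_grid,
                maximal_only=config.maximal_only,
                consequent=consequent,
                class_label=label,
                alpha=config.alpha,
                correction=config.correction,
            )
            X = list(cls_w) + list(other_w)
            y = [consequent] * len(cls_w) + ["other"] * len(other_w)
            return miner.fit(X, y)

        miner = mine()
        miners[(alphabet, label)] = miner
        tag = f"{alphabet}_{'pos' if label == 'N+' else 'neg'}"
        miner.preference_.to_tsv(out / f"preference_{tag}.tsv")
        write_rules_json(miner.rules_, out / f"rules_{tag}.json")
        rules_to_table(miner.rules_).to_csv(
            out / f"rules_{tag}.tsv", sep="\t", index=False
        )
        levels = sorted({t for r in miner.rules_ for t in r.thresholds})
        summary_rows[tag] = {
            "n_significantly_preferred": len(miner.eligible_items_),
            "n_association_patterns": miner.n_emitted_,
            "n_unique_association_patterns": miner.n_unique_,
            "support_level_range": (
                f"{levels[0]:g}-{levels[-1]:g}" if levels else None
            ),
        }

    # -- validation --------------------------------------------------------
    validation_out = {}
    if config.predictions:
        @_stage("validate[predictions]")
        def validate_predictions():
            pred, nonpred = read_prediction_tsv(config.predictions)
            reports = {}
            for name, site_list in [("predicted", pred), ("non_predicted", nonpred)]:
                usable = [s for s in site_list if s.protein_id in proteins]
                windows = ds.extract_windows(
                    proteins,
                    [ds.SiteRecord(s.protein_id, s.position) for s in usable],
                    flank=config.flank,
                )
                enc = GroupEncoder().fit(windows).transform(windows)
                reports[name] = conformity_report(
                    windows, miners[("raw", "N+")].rules_, name=name
                ).to_dict()
                reports[f"{name}_encoded"] = conformity_report(
                    enc, miners[("encoded", "N+")].rules_, name=f"{name}_encoded"
                ).to_dict()
            return reports

        validation_out["conformity"] = validate_predictions()

    if config.motifs:
        @_stage("validate[motifs]")
        def validate_motifs():
            entries = load_motif_table(config.motifs)
            result = validate_motif_table(
                entries, miners[("encoded", "N+")].rules_, flank=config.flank
            )
            return {
                "fraction_matched": result.fraction_matched,
                "skipped_rules": result.skipped_rules,
                "entries": result.table.to_dict(orient="records"),
            }

        validation_out["motifs"] = validate_motifs()

    if validation_out:
        (out / "validation.json").write_text(
            json.dumps(validation_out, indent=2, sort_keys=True) + "\n"
        )

    # -- summary (Table-1-shaped) and manifest ----------------------------
    summary = {
        "total_number_of_proteins": len(proteins),
        "number_of_targeted_sites": {
            "glycosylated": len(positives),
            "non_glycosylated": len(negatives),
        },
        "balanced_negatives": len(balanced),
        "datasets": summary_rows,
        "seed": config.seed,
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )

    inputs = {
        name: _sha256(Path(p))
        for name, p in [
            ("fasta", config.fasta),
            ("sites", config.sites),
            ("predictions", config.predictions),
            ("motifs", config.motifs),
        ]
        if p
    }
    outputs = {
        f.name: _sha256(f)
        for f in sorted(out.iterdir())
        if f.is_file() and f.name != "manifest.json"
    }
    try:
        pkg_version = _pkg_version("glycoctx")
    except Exception:  # not installed (e.g. run from a source tree)
        pkg_version = "unknown"
    manifest = {
        "config": {k: v for k, v in asdict(config).items()},
        "inputs_sha256": inputs,
        "outputs_sha256": outputs,
        "package_version": pkg_version,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=list) + "\n"
    )
    return summary
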