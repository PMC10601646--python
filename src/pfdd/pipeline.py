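"""End-to-end orchestration: clean -> audience-gate -> insight extractors.

The pipeline mirrors the production flow: posts are cleaned, an audience
classifier (trained with negative learning) labels each post patient /
caregiver / irrelevant, irrelevant posts are dropped, and the remaining
posts run through the insight extractors (medical sentiment, psychosocial
labeling, symptom severity).  One integer seed drives every stochastic
stage, so identical configuration and inputs reproduce byte-identical
outputs.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import negative_learning as nl
from .corpus import (
    PIIPatterns,
    PreprocessConfig,
    PreprocessReport,
    SocialPost,
    Source,
    load_corpus,
    preprocess,
)
from .medsent import HYPOTHESIS_SET_1, HYPOTHESIS_SET_2, consensus_classify
from .psychosocial import classify_psychosocial, load_taxonomy
from .severity import (
    ModifierLexicon,
    SeverityReport,
    SymptomTaxonomy,
    score_posts,
    severity_report,
)
from .synth import (
    DEFAULT_NAME_GAZETTEER,
    GeneratorConfig,
    MockNLIBackend,
    MockSentimentBackend,
    generate_corpus,
    generate_noisy_labels,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "export_report"]

DEFAULT_BLOCKED_SOURCES = frozenset({Source.PRINT_NEWS, Source.PODCAST_MESSAGE})


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for one pipeline run.

    Either ``input_path`` (a corpus file) or ``synthetic`` (generator
    settings) supplies the posts.  Stage toggles switch individual
    extractors off; the audience gate always runs.
    """

    out_dir: str = "pipeline_out"
    seed: int = 0
    input_path: str | None = None
    synthetic: GeneratorConfig | None = None
    blocked_sources: frozenset[Source] = DEFAULT_BLOCKED_SOURCES
    blocked_sub_sources: frozenset[str] = frozenset()
    name_gazetteer: tuple[str, ...] = DEFAULT_NAME_GAZETTEER
    alpha: float = 0.0  # label-noise rate for the synthetic training labels
    nl_config: nl.NLConfig | None = None
    medsent_enabled: bool = True
    medsent_threshold: float = 0.5  # mock-backend probabilities top out near 0.58
    psychosocial_enabled: bool = True
    abstain_threshold: float = 0.5
    severity_enabled: bool = True
    severity_top_n: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open(encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        for key in (
            "out_dir", "seed", "input_path", "alpha", "medsent_enabled",
            "medsent_threshold", "psychosocial_enabled", "abstain_threshold",
            "severity_enabled", "severity_top_n",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "blocked_sources" in raw:
            kwargs["blocked_sources"] = frozenset(Source(s) for s in raw["blocked_sources"])
        if "blocked_sub_sources" in raw:
            kwargs["blocked_sub_sources"] = frozenset(raw["blocked_sub_sources"])
        if "name_gazetteer" in raw:
            kwargs["name_gazetteer"] = tuple(raw["name_gazetteer"])
        if "synthetic" in raw:
            kwargs["synthetic"] = GeneratorConfig(**raw["synthetic"])
        if "nl" in raw:
            kwargs["nl_config"] = nl.NLConfig(**raw["nl"])
        return cls(**kwargs)


@dataclass
class PipelineResult:
    insights_path: Path
    report_path: Path
    insights: list[dict]
    preprocess_report: PreprocessReport
    severity: SeverityReport | None
    run_report: dict


def _audience_stage(
    posts: Sequence[SocialPost], config: PipelineConfig
) -> tuple[dict[str, tuple[str, float]], dict]:
    """Train on the synthetic truth labels (with optional injected noise)
    and predict an audience label + confidence for every cleaned post."""
    if config.synthetic is None:
        raise ValueError(
            "audience stage needs training labels; supply a synthetic config "
            "or a pre-trained model"
        )
    corpus = generate_corpus(config.synthetic)
    examples = generate_noisy_labels(corpus, config.alpha, config.seed)
    nl_cfg = config.nl_config or nl.NLConfig(seed=config.seed)
    backend, history = nl.train(examples, nl_cfg)
    probs = backend.predict_proba([p.text for p in posts])
    out: dict[str, tuple[str, float]] = {}
    for post, p in zip(posts, probs):
        k = int(p.argmax())
        out[post.post_id] = (nl.AUDIENCE_LABELS[k], float(p[k]))
    stage_info = {
        "n_train": len(examples),
        "alpha": config.alpha,
        "regime": nl_cfg.regime,
        "epochs": len(history),
        "final_accuracy_given": history[-1].accuracy_given,
    }
    return out, stage_info


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the staged pipeline and write insights + run report."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    run_report: dict = {"seed": config.seed, "stages": {}}

    # -- input ---------------------------------------------------------------
    if config.input_path is not None:
        posts = load_corpus(config.input_path)
    elif config.synthetic is not None:
        posts = list(generate_corpus(config.synthetic).posts)
    else:
        raise ValueError("config must name input_path or synthetic")
    run_report["stages"]["input"] = {"n_posts": len(posts)}

    # -- preprocessing ---------------------------------------------------------
    pp_config = PreprocessConfig(
        blocked_sources=config.blocked_sources,
        blocked_sub_sources=config.blocked_sub_sources,
        pii_patterns=PIIPatterns(name_gazetteer=config.name_gazetteer),
    )
    clean, pp_report = preprocess(posts, pp_config)
    run_report["stages"]["preprocess"] = pp_report.to_dict()

    # -- audience classification + gate ---------------------------------------
    audience, stage_info = _audience_stage(clean, config)
    run_report["stages"]["audience"] = stage_info
    gated = [p for p in clean if audience[p.post_id][0] != "irrelevant"]
    run_report["stages"]["audience"]["n_gated_in"] = len(gated)

    # -- extractors ------------------------------------------------------------
    nli = MockNLIBackend()
    sentiment = MockSentimentBackend()
    taxonomy = load_taxonomy()
    symptom_tax = SymptomTaxonomy()
    lexicon = ModifierLexicon()

    mentions_by_post: dict[str, list[dict]] = {}
    sev_report: SeverityReport | None = None
    if config.severity_enabled:
        mentions = score_posts(gated, symptom_tax, sentiment, lexicon)
        for m in mentions:
            mentions_by_post.setdefault(m.post_id, []).append(
                {k: v for k, v in m.to_record().items() if k != "post_id"}
            )
        sev_report = severity_report(mentions, top_n=config.severity_top_n)
        run_report["stages"]["severity"] = {
            "n_mentions": len(mentions),
            "n_symptoms": len(sev_report.severities),
        }

    insights: list[dict] = []
    n_medsent_accepted = 0
    n_psy_labeled = 0
    for post in gated:
        label, conf = audience[post.post_id]
        rec: dict = {
            "post_id": post.post_id,
            "audience_label": label,
            "audience_confidence": round(conf, 6),
        }
        if config.medsent_enabled:
            pred = consensus_classify(
                post.text, HYPOTHESIS_SET_1, HYPOTHESIS_SET_2, backend=nli
            )
            kept = pred.accepted and pred.probability >= config.medsent_threshold
            rec["medsent_label"] = pred.label if kept else None
            rec["medsent_probability"] = (
                round(pred.probability, 6) if kept else None
            )
            rec["medsent_accepted"] = bool(kept)
            n_medsent_accepted += int(kept)
        if config.psychosocial_enabled:
            psy = classify_psychosocial(
                post.text, taxonomy, nli, abstain_threshold=config.abstain_threshold
            )
            rec["psychosocial_label"] = psy.label
            rec["psychosocial_reason"] = psy.reason
            rec["psychosocial_abstained"] = psy.abstained
            n_psy_labeled += int(not psy.abstained)
        if config.severity_enabled:
            rec["symptom_mentions"] = mentions_by_post.get(post.post_id, [])
        insights.append(rec)

    if config.medsent_enabled:
        run_report["stages"]["medsent"] = {"n_accepted": n_medsent_accepted}
    if config.psychosocial_enabled:
        run_report["stages"]["psychosocial"] = {"n_labeled": n_psy_labeled}

    # -- outputs ----------------------------------------------------------------
    insights_path = out_dir / "insights.jsonl"
    with insights_path.open("w", encoding="utf-8") as fh:
        for rec in insights:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
    report_path = out_dir / "run_report.json"
    with report_path.open("w", encoding="utf-8") as fh:
        json.dump(run_report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if sev_report is not None:
        with (out_dir / "severity.csv").open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=["symptom", "mentions", "severity", "rank"])
            writer.writeheader()
            writer.writerows(sev_report.to_rows())

    return PipelineResult(
        insights_path=insights_path,
        report_path=report_path,
        insights=insights,
        preprocess_report=pp_report,
        severity=sev_report,
        run_report=run_report,
    )


def export_report(
    insights: Sequence[Mapping], out_dir: str | Path, format: str = "csv"
) -> dict[str, Path]:
    """Flat summary tables: audience counts, sentiment counts, psychosocial
    counts, severity top-N.  Empty input yields header-only files."""
    if format not in ("csv", "jsonl"):
        raise ValueError(f"unsupported format: {format!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def _count(key: str) -> list[dict]:
        counts: dict[str, int] = {}
        for rec in insights:
            val = rec.get(key)
            if val is not None:
                counts[val] = counts.get(val, 0) + 1
        return [
            {"value": v, "count": c}
            for v, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        ]

    # distinct-post severity from insight records
    sev_posts: dict[str, set] = {}
    for rec in insights:
        for m in rec.get("symptom_mentions", []):
            if m.get("tonality") == "negative":
                sev_posts.setdefault(m["symptom"], set()).add(rec["post_id"])
    severity_rows = [
        {"value": s, "count": len(ids)}
        for s, ids in sorted(sev_posts.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    ]

    tables = {
        "audience_counts": _count("audience_label"),
        "medsent_counts": _count("medsent_label"),
        "psychosocial_counts": _count("psychosocial_label"),
        "severity_top": severity_rows,
    }
    paths: dict[str, Path] = {}
    for name, rows in tables.items():
        if format == "csv":
            path = out_dir / f"{name}.csv"
            with path.open("w", newline="", encoding="utf-8") as fh:
                writer = csv.DictWriter(fh, fieldnames=["value", "count"])
                writer.writeheader()
                writer.writerows(rows)
        else:
            path = out_dir / f"{name}.jsonl"
            with path.open("w", encoding="utf-8") as fh:
                for row in rows:
                    fh.write(json.dumps(row, sort_keys=True) + "\n")
        paths[name] = path
    return paths
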