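"""End-to-end orchestration: corpus -> topics -> features -> synchrony ->
model comparison -> explanation, with seeded determinism and a report
bundle of data artifacts.

The bundle mirrors the analysis's standard outputs: a corpus summary, the
tagged feature table, the algorithm x feature-source MAE grid, the signed
cumulative-SHAP decomposition by source and type, the feature ranking
with its cumulative-influence curve, the incremental-selection curve, the
attribution clustering, and selected local decompositions — plus a run
manifest (config hash, seeds, versions) sufficient to reproduce every
deterministic file byte-identically.

Report CSVs round to 4 decimals; full-precision sidecars carry the same
numbers for programmatic re-aggregation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import vocab
from .corpus import (GeneratorConfig, OutcomeModel, SynchronyControls,
                     default_outcome_model, generate_corpus, read_corpus,
                     write_corpus)
from .embedding import EmbeddingParams
from .explain import (cluster_features, compute_shap, grouped_decomposition,
                      incremental_selection, local_explanation,
                      rank_features, share_of_total)
from .features import FeatureTable, build_feature_table
from .models import ModelSpec, compare_feature_sets
from .synchrony import append_synchrony
from .topics import build_topic_model
from .vocab import default_group_map, default_lexicon

__all__ = ["RunConfig", "ReportBundle", "validate_config", "run_pipeline"]

log = logging.getLogger("counselhelp.pipeline")

_DEFAULT_SOURCE_SETS = (
    ("counselor",),
    ("counselee",),
    ("synchrony",),
    ("counselee", "counselor", "synchrony"),
)


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Exactly one of ``corpus_path`` / ``generator`` feeds the run.  The
    global ``seed`` propagates to every stochastic stage (generation,
    embedding, clustering, fold shuffling, forests, explainers).
    """

    output_dir: Path
    corpus_path: Path | None = None
    generator: GeneratorConfig | None = None
    seed: int = 0
    # stage toggles
    run_topics: bool = True
    run_models: bool = True
    run_explain: bool = True
    # topic stage
    embedding_dimension: int = 50
    embedding_window: int = 0
    embedding_min_count: int = 3
    expansion_threshold: float = 0.5
    k_min: int = 2
    k_max: int = 10
    k_override: int | None = None
    #: drop closed-class glue before embedding training (and only there);
    #: None -> the synthetic language's own stop-word list
    stopwords_path: Path | None = None
    use_stopwords: bool = True
    # model stage
    n_folds: int = 10
    algorithms: tuple[str, ...] = ("linear_regression", "ridge", "lasso",
                                   "svr", "random_forest")
    rf_trees: int = 500
    rf_max_depth: int | None = None
    log1p_outcome: bool = False
    # explanation stage
    explainer_rf_trees: int = 300
    explainer_rf_max_depth: int | None = 8
    selection_max_k: int = 30
    n_style_clusters: int = 5
    local_indices: tuple[int, ...] = (0,)

    def validate(self) -> "RunConfig":
        if (self.corpus_path is None) == (self.generator is None):
            raise ValueError(
                "exactly one of corpus_path / generator must be given")
        if self.corpus_path is not None and not Path(self.corpus_path).exists():
            raise ValueError(f"corpus_path: {self.corpus_path} does not exist")
        if self.n_folds < 2:
            raise ValueError(f"n_folds: {self.n_folds} must be >= 2")
        if not (2 <= self.k_min <= self.k_max):
            raise ValueError(f"k_min/k_max: ({self.k_min}, {self.k_max})")
        if self.selection_max_k < 1:
            raise ValueError("selection_max_k: must be >= 1")
        if self.n_style_clusters < 2:
            raise ValueError("n_style_clusters: must be >= 2")
        if self.generator is not None:
            self.generator.validate()
        return self


def validate_config(raw: Mapping[str, Any] | RunConfig) -> RunConfig:
    """Build a normalized :class:`RunConfig` from a plain mapping (e.g. a
    parsed YAML file), rejecting unknown keys and invalid ranges."""
    if isinstance(raw, RunConfig):
        return raw.validate()
    raw = dict(raw)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    for key in raw:
        if key not in known:
            raise ValueError(f"unknown config key {key!r}")
    gen = raw.get("generator")
    if isinstance(gen, Mapping):
        gen = dict(gen)
        sc = gen.pop("synchrony_controls", None)
        om = gen.pop("outcome_model", None)
        gen_known = {f.name for f in dataclasses.fields(GeneratorConfig)}
        for key in gen:
            if key not in gen_known:
                raise ValueError(f"unknown config key generator.{key!r}")
        if "category_rate_ranges" in gen:
            gen["category_rate_ranges"] = {
                k: tuple(v) for k, v in gen["category_rate_ranges"].items()}
        if "topic_rate_range" in gen:
            gen["topic_rate_range"] = tuple(gen["topic_rate_range"])
        kwargs = dict(gen)
        if sc is not None:
            kwargs["synchrony_controls"] = SynchronyControls(**sc)
        if om is not None:
            kwargs["outcome_model"] = OutcomeModel(**om)
        raw["generator"] = GeneratorConfig(**kwargs)
    if "output_dir" in raw:
        raw["output_dir"] = Path(raw["output_dir"])
    if "corpus_path" in raw and raw["corpus_path"] is not None:
        raw["corpus_path"] = Path(raw["corpus_path"])
    for tup_key in ("algorithms", "local_indices"):
        if tup_key in raw:
            raw[tup_key] = tuple(raw[tup_key])
    return RunConfig(**raw).validate()


@dataclass
class ReportBundle:
    """Paths and in-memory objects produced by one pipeline run."""

    output_dir: Path
    corpus_summary: dict
    feature_table: FeatureTable
    model_grid: pd.DataFrame | None = None
    decomposition_by_source: pd.DataFrame | None = None
    decomposition_table: pd.DataFrame | None = None
    ranking: pd.DataFrame | None = None
    selection_curve: pd.DataFrame | None = None
    best_k: int | None = None
    clustering: dict[str, int] | None = None
    chosen_k: dict[str, int] | None = None
    local: list[dict] | None = None
    manifest: dict | None = None
    files: dict[str, Path] = field(default_factory=dict)


def _write_csv(df: pd.DataFrame, path: Path, index: bool = True) -> Path:
    """4-decimal report CSV plus a full-precision sidecar."""
    df.round(4).to_csv(path, index=index)
    df.to_csv(path.with_name(path.stem + "_full.csv"), index=index,
              float_format="%.17g")
    return path


def _table2_shape(decomp_by_type_source: pd.DataFrame) -> pd.DataFrame:
    """Pivot (source, type) decomposition rows into the wide report:
    one row per type, negative/positive/total per source, final total."""
    sources = ["counselor", "counselee", "synchrony"]
    types = list(dict.fromkeys(t for (_, t) in decomp_by_type_source.index))
    out = {}
    for t in sorted(types):
        row = {}
        total = 0.0
        for s in sources:
            key = (s, t)
            if key in decomp_by_type_source.index:
                rec = decomp_by_type_source.loc[key]
                row[f"{s}_negative"] = rec["negative"]
                row[f"{s}_positive"] = rec["positive"]
                row[f"{s}_total"] = rec["total"]
                total += rec["total"]
            else:
                row[f"{s}_negative"] = np.nan
                row[f"{s}_positive"] = np.nan
                row[f"{s}_total"] = np.nan
        row["total_effect"] = total
        out[t] = row
    df = pd.DataFrame(out).T
    df.index.name = "type"
    return df


def run_pipeline(config: RunConfig | Mapping[str, Any]) -> ReportBundle:
    """Execute the enabled stages in order and write the report bundle."""
    cfg = validate_config(config)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(cfg, out, files)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(cfg: RunConfig, out: Path, files: dict[str, Path]) -> ReportBundle:
    # ------------------------------------------------------------------ data
    if cfg.generator is not None:
        gen = dataclasses.replace(cfg.generator, seed=cfg.seed)
        corpus, truth = generate_corpus(gen)
        files["corpus"] = out / "corpus.jsonl"
        write_corpus(corpus, files["corpus"])
        log.info("generated corpus: %d pairs, seed %d", len(corpus), cfg.seed)
    else:
        corpus = read_corpus(cfg.corpus_path)
        truth = None
        log.info("read corpus: %d pairs from %s", len(corpus),
                 cfg.corpus_path)
    votes = np.array([p.helpful_votes for p in corpus], dtype=float)
    q_lens = [len(p.question_tokens) for p in corpus]
    r_lens = [len(p.response_tokens) for p in corpus]
    summary = {
        "n_pairs": len(corpus),
        "votes_mean": float(votes.mean()) if len(corpus) else 0.0,
        "votes_min": int(votes.min()) if len(corpus) else 0,
        "votes_max": int(votes.max()) if len(corpus) else 0,
        "question_mean_tokens": float(np.mean(q_lens)) if q_lens else 0.0,
        "response_mean_tokens": float(np.mean(r_lens)) if r_lens else 0.0,
    }
    files["summary"] = out / "corpus_summary.json"
    files["summary"].write_text(json.dumps(summary, indent=2, sort_keys=True))

    # ---------------------------------------------------------------- topics
    chosen_k: dict[str, int] = {}
    if cfg.run_topics:
        docs = [p.question_tokens for p in corpus] + \
               [p.response_tokens for p in corpus]
        seeds = {"symptom": vocab.topic_seeds("symptom"),
                 "factor": vocab.topic_seeds("factor")}
        if not cfg.use_stopwords:
            stop = None
        elif cfg.stopwords_path is not None:
            from .lexicon import read_stopwords
            stop = read_stopwords(cfg.stopwords_path)
        else:
            stop = vocab.synthetic_stopwords()
        tm = build_topic_model(
            docs, seeds,
            params=EmbeddingParams(dimension=cfg.embedding_dimension,
                                   window=cfg.embedding_window,
                                   min_count=cfg.embedding_min_count,
                                   seed=cfg.seed),
            threshold=cfg.expansion_threshold,
            k_range=range(cfg.k_min, cfg.k_max + 1),
            k_override=cfg.k_override, stopwords=stop, seed=cfg.seed)
        symptom_lex = tm.lexicons("symptom")
        factor_lex = tm.lexicons("factor")
        topic_dir = out / "topics"
        topic_dir.mkdir(exist_ok=True)
        for part in ("symptom", "factor"):
            chosen_k[part] = tm.chosen_k(part)
            log.info("topics[%s]: chosen k = %d (silhouette %s)", part,
                     chosen_k[part],
                     {k: round(v, 4)
                      for k, v in tm.selections[part].silhouette_trace.items()})
            lex_path = topic_dir / f"{part}_lexicons.json"
            lex_path.write_text(json.dumps(
                {nm: sorted(ws) for nm, ws in tm.lexicons(part).items()},
                indent=2, sort_keys=True))
            files[f"topics_{part}"] = lex_path
            trace = pd.DataFrame(
                sorted(tm.selections[part].silhouette_trace.items()),
                columns=["k", "silhouette"])
            _write_csv(trace, topic_dir / f"{part}_silhouette.csv",
                       index=False)
    else:
        # truth lexicons: the generator's planted topic pools
        symptom_lex = vocab.topic_lexicons("symptom")
        factor_lex = vocab.topic_lexicons("factor")
        log.info("topics stage skipped; using planted topic lexicons")

    # -------------------------------------------------------------- features
    lexicon = default_lexicon()
    gmap = default_group_map()
    table = build_feature_table(corpus, lexicon, gmap)
    table = append_synchrony(table, corpus, symptom_lex, factor_lex)
    files["features"], files["feature_tags"] = table.write(out / "features")
    log.info("feature table: %d rows x %d columns; %d empty documents; "
             "%d degenerate pairs", len(table.data), table.data.shape[1],
             len(table.empty_documents), table.n_degenerate_pairs)

    y = np.log1p(votes) if cfg.log1p_outcome else votes

    bundle = ReportBundle(output_dir=out, corpus_summary=summary,
                          feature_table=table, chosen_k=chosen_k or None,
                          files=files)

    # ---------------------------------------------------------------- models
    if cfg.run_models:
        rf_hp = {"n_estimators": cfg.rf_trees}
        if cfg.rf_max_depth is not None:
            rf_hp["max_depth"] = cfg.rf_max_depth
        specs = [ModelSpec(a, rf_hp if a == "random_forest" else {},
                           seed=cfg.seed)
                 for a in cfg.algorithms]
        grid, _ = compare_feature_sets(table, y, specs, _DEFAULT_SOURCE_SETS,
                                       n_folds=cfg.n_folds, cv_seed=cfg.seed)
        files["model_grid"] = _write_csv(grid, out / "model_grid.csv")
        bundle.model_grid = grid
        log.info("model grid best cell: %.4f",
                 grid.drop(index="source_mean")
                     .drop(columns="algorithm_mean").min().min())

    # --------------------------------------------------------------- explain
    if cfg.run_explain:
        exp_hp = {"n_estimators": cfg.explainer_rf_trees}
        if cfg.explainer_rf_max_depth is not None:
            exp_hp["max_depth"] = cfg.explainer_rf_max_depth
        spec = ModelSpec("random_forest", exp_hp, seed=cfg.seed)
        from .models import fit_regressor
        X = table.data.to_numpy(dtype=float)
        model = fit_regressor(X, y, spec)
        shap = compute_shap(model, table.data, method="exact-tree")
        files["shap_matrix"] = out / "shap_matrix.csv"
        shap_df = shap.to_frame()
        shap_df.insert(0, "base_value", shap.base_value)
        shap_df.to_csv(files["shap_matrix"], index=False,
                       float_format="%.17g")

        src_grouping = {f: table.tags[f][0] for f in shap.feature_names}
        by_source = grouped_decomposition(shap, src_grouping, "source")
        files["decomposition_by_source"] = _write_csv(
            by_source.table, out / "decomposition_by_source.csv")
        bundle.decomposition_by_source = by_source.table
        log.info("source shares: %s",
                 {k: round(v, 2) for k, v in
                  share_of_total(by_source).items()})

        pair_grouping = {f: f"{table.tags[f][0]}|{table.tags[f][1]}"
                         for f in shap.feature_names}
        by_pair = grouped_decomposition(shap, pair_grouping, "source|type")
        wide_idx = pd.MultiIndex.from_tuples(
            [tuple(g.split("|", 1)) for g in by_pair.table.index])
        by_pair_table = by_pair.table.copy()
        by_pair_table.index = wide_idx
        table2 = _table2_shape(by_pair_table)
        files["decomposition"] = _write_csv(table2, out / "decomposition.csv")
        bundle.decomposition_table = table2

        ranking = rank_features(shap)
        files["ranking"] = _write_csv(ranking, out / "ranking.csv",
                                      index=False)
        bundle.ranking = ranking

        curve, best_k = incremental_selection(
            table, y, ranking["feature"].tolist(), spec,
            n_folds=cfg.n_folds, cv_seed=cfg.seed, max_k=cfg.selection_max_k)
        files["selection"] = _write_csv(curve, out / "selection_curve.csv",
                                        index=False)
        bundle.selection_curve = curve
        bundle.best_k = best_k
        log.info("incremental selection: best k = %d (MAE %.4f)", best_k,
                 float(curve["mae"].min()))

        fc = cluster_features(shap, n_clusters=cfg.n_style_clusters)
        assign = pd.DataFrame(sorted(fc.assignments.items()),
                              columns=["feature", "cluster"])
        files["clusters"] = out / "clusters.csv"
        assign.to_csv(files["clusters"], index=False)
        np.savetxt(out / "cluster_linkage.csv", fc.linkage_matrix,
                   delimiter=",", fmt="%.17g")
        bundle.clustering = fc.assignments

        locals_: list[dict] = []
        for i in cfg.local_indices:
            if 0 <= i < len(table.data):
                le = local_explanation(model, shap, i)
                locals_.append({
                    "observation": le.observation,
                    "base_value": le.base_value,
                    "prediction": le.prediction,
                    "contributions": le.contributions[:20],
                })
        files["local"] = out / "local_explanations.json"
        files["local"].write_text(json.dumps(locals_, indent=2))
        bundle.local = locals_
    else:
        log.info("explanation stage skipped")

    # --------------------------------------------------------------- manifest
    cfg_dict = dataclasses.asdict(cfg)
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
    import sklearn
    manifest = {
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": cfg.seed,
        "chosen_k": chosen_k,
        "best_k": bundle.best_k,
        "skipped_stages": [s for s, on in
                           [("topics", cfg.run_topics),
                            ("models", cfg.run_models),
                            ("explain", cfg.run_explain)] if not on],
        "versions": {"numpy": np.__version__, "pandas": pd.__version__,
                     "sklearn": sklearn.__version__},
    }
    files["manifest"] = out / "manifest.json"
    files["manifest"].write_text(json.dumps(manifest, indent=2,
                                            sort_keys=True))
    bundle.manifest = manifest
    bundle.files = files
    return bundle
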