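"""Pre/post disturbance comparison pipeline.

Takes two analysis-ready webs (read from files or generated synthetically),
computes global metrics, node centralities, trophic levels and energy
fluxes for each, and assembles a comparison report: environmental percent
changes, paired global metrics, per-node trophic-level shifts over the
shared nodes, and flux summaries.  Everything the report contains is
recomputed from the emitted intermediate files; a rerun with the same
inputs is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import flux as flux_mod
from . import metrics as metrics_mod
from .core import AggregationScheme, FoodWeb, FoodWebError, aggregate, read_web, symmetrize, write_web
from .flux import FluxParameters
from .synthetic import Perturbation, SyntheticWebSpec, generate_disturbance_pair
from .trophic import TrophicLevels, trophic_levels

logger = logging.getLogger(__name__)

#: TL shifts are classified at the reporting precision (2 dp): an absolute
#: difference below 0.005 rounds to no change.
TL_NO_CHANGE_THRESHOLD = 0.005


def parse_bounded(value: object) -> float:
    """Parse a numeric table cell, treating a ``<x`` bound as its value x."""
    text = str(value).strip()
    if text.startswith("<") or text.startswith(">"):
        text = text[1:]
    return float(text)


def percent_change(pre: object, post: object) -> float:
    """(post - pre)/pre * 100; bounds like ``<1.00`` are parsed as 1.00."""
    pre_v, post_v = parse_bounded(pre), parse_bounded(post)
    if pre_v == 0:
        raise FoodWebError("percent change undefined for a zero baseline value")
    return (post_v - pre_v) / pre_v * 100.0


def environmental_changes(table: pd.DataFrame) -> pd.DataFrame:
    """Recompute percent changes for an environmental pre/post table."""
    out = table.copy()
    out["percent_change"] = [
        round(percent_change(pre, post), 2)
        for pre, post in zip(out["pre_value"], out["post_value"])
    ]
    return out


@dataclass(frozen=True)
class ComparisonReport:
    """Paired analysis of a baseline and a disturbed web."""

    global_metrics: pd.DataFrame  # metric x {pre, post}
    shared_nodes: pd.DataFrame  # node, TL_pre, TL_post, delta, classification
    flux_summary: pd.DataFrame | None = None  # web x {n_fluxes, total, diversity}
    environmental: pd.DataFrame | None = None

    @property
    def n_shared(self) -> int:
        return len(self.shared_nodes)

    def classification_counts(self) -> dict[str, int]:
        counts = self.shared_nodes["classification"].value_counts().to_dict()
        return {k: int(counts.get(k, 0)) for k in ("decrease", "no change", "increase")}

    def to_text(self) -> str:
        lines = ["Comparison report", "=" * 17, ""]
        lines.append("Global metrics (pre vs post):")
        lines.append(self.global_metrics.to_string())
        lines.append("")
        counts = self.classification_counts()
        lines.append(
            f"Shared nodes: {self.n_shared} "
            f"(decrease {counts['decrease']}, no change {counts['no change']}, "
            f"increase {counts['increase']})"
        )
        lines.append(self.shared_nodes.to_string(index=False))
        if self.flux_summary is not None:
            lines += ["", "Flux summaries:", self.flux_summary.to_string()]
        if self.environmental is not None:
            lines += ["", "Environmental change:", self.environmental.to_string(index=False)]
        return "\n".join(lines) + "\n"


def classify_tl_shift(pre: float, post: float) -> str:
    delta = post - pre
    if abs(delta) < TL_NO_CHANGE_THRESHOLD:
        return "no change"
    return "increase" if delta > 0 else "decrease"


def compare_webs(
    web_pre: FoodWeb,
    web_post: FoodWeb,
    metrics_pre: metrics_mod.GlobalMetrics,
    metrics_post: metrics_mod.GlobalMetrics,
    tl_pre: TrophicLevels,
    tl_post: TrophicLevels,
    flux_summary: Mapping[str, Mapping[str, float]] | None = None,
    environmental: pd.DataFrame | None = None,
) -> ComparisonReport:
    """Assemble the paired report from precomputed per-web results."""
    gm = pd.DataFrame(
        {"pre": metrics_pre.as_series(), "post": metrics_post.as_series()}
    )
    shared = sorted(set(web_pre.nodes) & set(web_post.nodes))
    rows = []
    for node in shared:
        pre_tl = round(tl_pre[node], 2)
        post_tl = round(tl_post[node], 2)
        rows.append(
            {
                "node": node,
                "TL_pre": pre_tl,
                "TL_post": post_tl,
                "delta": round(post_tl - pre_tl, 2),
                "classification": classify_tl_shift(pre_tl, post_tl),
            }
        )
    shared_df = pd.DataFrame(
        rows, columns=["node", "TL_pre", "TL_post", "delta", "classification"]
    )
    flux_df = None
    if flux_summary is not None:
        flux_df = pd.DataFrame(flux_summary).T[
            ["n_fluxes", "total_flux", "shannon_diversity"]
        ]
    return ComparisonReport(gm, shared_df, flux_df, environmental)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalysisConfig:
    """Inputs of one full run: either file paths or a synthetic spec.

    ``edges/attrs`` (and the optional ``_post`` pair) point at CSV files;
    alternatively ``synthetic`` + ``perturbation`` generate the pair.  An
    aggregation scheme, when given, is applied before analysis.
    """

    edges: Path | None = None
    attrs: Path | None = None
    edges_post: Path | None = None
    attrs_post: Path | None = None
    synthetic: SyntheticWebSpec | None = None
    perturbation: Perturbation | None = None
    scheme: AggregationScheme | None = None
    flux_params: FluxParameters = field(default_factory=FluxParameters)
    compute_fluxes: bool = True
    out_dir: Path = Path("trophoweb_out")


def _load_webs(config: AnalysisConfig) -> tuple[FoodWeb, FoodWeb | None]:
    if config.synthetic is not None:
        pert = config.perturbation
        if pert is None:
            from .synthetic import generate_niche_web

            return generate_niche_web(config.synthetic), None
        return generate_disturbance_pair(config.synthetic, pert)
    if config.edges is None or config.attrs is None:
        raise FoodWebError("config needs either file paths or a synthetic spec")
    web = read_web(config.edges, config.attrs, label="pre")
    web_post = None
    if config.edges_post is not None:
        web_post = read_web(config.edges_post, config.attrs_post, label="post")
    return web, web_post


def _analyse_one(
    web: FoodWeb, config: AnalysisConfig, tag: str, out: Path, log: list[str]
) -> tuple[metrics_mod.GlobalMetrics, TrophicLevels, dict[str, float] | None]:
    try:
        if config.scheme is not None:
            web = aggregate(web, config.scheme)
            log.append(f"[{tag}] aggregated to {web.n_nodes} nodes / {web.n_edges} links")
        web.validate_analysis_ready()
        write_web(web, out / f"{tag}_edges.csv", out / f"{tag}_attributes.csv",
                  out / f"{tag}_adjacency.csv")

        und = symmetrize(web)
        gm = metrics_mod.global_metrics(und)
        gm.as_series().rename_axis("metric").to_frame("value").to_csv(
            out / f"{tag}_global_metrics.csv"
        )
        tl = trophic_levels(web)
        nm = metrics_mod.node_metrics(und)
        nm["TL"] = [round(tl[n], 2) for n in nm["node"]]
        nm.to_csv(out / f"{tag}_node_metrics.csv", index=False)
        tl.as_series().rename_axis("node").to_frame("TL").to_csv(
            out / f"{tag}_trophic_levels.csv"
        )
        log.append(f"[{tag}] global metrics: " +
                   ", ".join(f"{k}={v}" for k, v in gm.as_series().items()))

        summary = None
        if config.compute_fluxes:
            fluxes, flux_web = flux_mod.compute_fluxes(web, config.flux_params)
            dropped = sorted(set(web.nodes) - set(flux_web.nodes))
            if dropped:
                log.append(f"[{tag}] WARN: nodes dropped from fluxes (no data): {dropped}")
            fluxes.to_long().to_csv(out / f"{tag}_fluxes.csv", index=False)
            fluxes.matrix.to_csv(out / f"{tag}_flux_matrix.csv", index_label="prey")
            flux_mod.flux_matrix_log10(fluxes, tl).to_csv(
                out / f"{tag}_flux_matrix_log10.csv", index_label="prey"
            )
            summary = flux_mod.flux_summaries(fluxes)
            log.append(f"[{tag}] flux summary: " +
                       ", ".join(f"{k}={v:.6g}" for k, v in summary.items()))
        return gm, tl, summary
    except FoodWebError as exc:
        raise FoodWebError(f"stage {tag!r}: {exc}") from exc


def run_full_analysis(config: AnalysisConfig) -> Path:
    """Run the whole analysis and write every table under ``config.out_dir``.

    Deterministic: no timestamps enter the outputs, so reruns with the same
    config are byte-identical (including the synthetic branch at fixed
    seed).  Returns the output directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # the log materializes every effective parameter (but not the output
    # path, so reruns into different directories stay byte-identical)
    log: list[str] = ["trophoweb run"]
    for name in ("edges", "attrs", "edges_post", "attrs_post", "synthetic",
                 "perturbation", "flux_params", "compute_fluxes"):
        log.append(f"  {name}: {getattr(config, name)}")
    log.append(
        f"  scheme: {len(config.scheme.mapping)} taxa" if config.scheme else "  scheme: None"
    )

    web_pre, web_post = _load_webs(config)
    results = {}
    results["pre"] = _analyse_one(web_pre, config, "pre", out, log)
    if web_post is not None:
        results["post"] = _analyse_one(web_post, config, "post", out, log)

        gm_pre, tl_pre, fs_pre = results["pre"]
        gm_post, tl_post, fs_post = results["post"]
        flux_summary = None
        if fs_pre is not None and fs_post is not None:
            flux_summary = {"pre": fs_pre, "post": fs_post}
        pre_agg = aggregate(web_pre, config.scheme) if config.scheme else web_pre
        post_agg = aggregate(web_post, config.scheme) if config.scheme else web_post
        report = compare_webs(pre_agg, post_agg, gm_pre, gm_post, tl_pre, tl_post,
                              flux_summary)
        report.shared_nodes.to_csv(out / "comparison_shared_nodes.csv", index=False)
        report.global_metrics.rename_axis("metric").to_csv(out / "comparison_global_metrics.csv")
        (out / "comparison_report.txt").write_text(report.to_text())
        log.append(f"comparison: {report.n_shared} shared nodes, "
                   f"{report.classification_counts()}")

    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    return out
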