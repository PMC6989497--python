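"""End-to-end orchestration of the margin-prediction pipeline.

``run_all`` executes simulate -> preprocess -> model-order study -> PCA
study -> repeated clustering -> expert comparison from one YAML-serializable
configuration, with per-stage seeds derived from a single master seed by
fixed offsets so each stage is independently re-runnable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as cl
from . import dimred, expert, preprocess, synth

__all__ = [
    "PipelineConfig",
    "RunReport",
    "derive_seed",
    "run_all",
    "render_table",
    "gap_model_order_study",
    "component_count_study",
]

log = logging.getLogger("ppixmargin")

# fixed per-stage seed offsets (documented contract: stages re-runnable alone)
_STAGE_OFFSETS = {
    "simulate": 11,
    "embed": 101,
    "model_order": 211,
    "runs": 307,
    "compare": 401,
}


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(master_seed) * 9973 + _STAGE_OFFSETS[stage]) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run (YAML round-trip stable)."""

    master_seed: int = 0
    out_dir: str = "ppixmargin_run"
    # dataset
    class_counts: dict = field(
        default_factory=lambda: {"core": 10, "hd_margin": 24, "ld_margin": 9, "healthy": 7}
    )
    n_patients: int = 10
    class_params: dict = field(default_factory=dict)  # label -> field overrides
    grid: dict = field(
        default_factory=lambda: {"start_nm": 435.0, "stop_nm": 840.0, "n_points": 900}
    )
    write_raw_frames: bool = False
    # preprocessing
    energy: str = "l1"
    # reduction
    dim: int = 3
    perplexity: float = 10.0
    # clustering
    cluster_method: str = "kmeans"
    k: int | str = 4  # integer or "auto"
    k_min: int = 1
    k_max: int = 8
    n_runs: int = 20
    gap_B: int = 50
    gap_rule: str = "argmax"
    # space for the BIC/gap curves: the criterion study sits upstream of the
    # t-SNE clustering embedding, so a PCA 3-D reduction is the default
    model_order_space: str = "pca"  # pca | tsne | full
    # expert fit
    fit_window: dict = field(default_factory=lambda: {"low_nm": 585.0, "high_nm": 640.0})
    make_plots: bool = True

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    # --- resolved domain objects -------------------------------------
    def build_grid(self) -> synth.WavelengthGrid:
        return synth.make_wavelength_grid(**self.grid)

    def build_class_params(self) -> dict[str, synth.TissueClassParams]:
        table = synth.default_class_params()
        for label, overrides in self.class_params.items():
            table[label] = dataclasses.replace(table[label], **overrides)
        return table

    def build_dataset_spec(self) -> synth.DatasetSpec:
        return synth.DatasetSpec(
            class_counts=dict(self.class_counts),
            n_patients=self.n_patients,
            seed=derive_seed(self.master_seed, "simulate"),
        )

    def build_window(self) -> expert.FitWindow:
        return expert.FitWindow(**self.fit_window)


def _fmt_mean(m: float) -> str:
    text = f"{m:.1f}"
    return text[:-2] if text.endswith(".0") else text


def render_table(summary: cl.ConfusionSummary, style: str = "table1") -> str:
    """Render an averaged confusion matrix with each cell reading
    ``mean (percent%) sigma = sd``."""
    if style != "table1":
        raise ValueError(f"unknown table style {style!r}")
    names = {"core": "Core", "hd_margin": "HD Margin", "ld_margin": "LD Margin",
             "healthy": "Healthy"}
    header = [""] + [f"Predicted {names.get(c, c)}" for c in summary.classes]
    rows = [header]
    for i, c in enumerate(summary.classes):
        label = f"True {names.get(c, c)} ({_fmt_mean(summary.row_totals[i])})"
        cells = [label]
        for j in range(len(summary.classes)):
            pct = int(np.floor(summary.percent[i, j] + 0.5))
            cells.append(
                f"{_fmt_mean(summary.mean_counts[i, j])} ({pct}%) "
                f"σ = {summary.sigma[i, j]:.2f}"
            )
        rows.append(cells)
    widths = [max(len(r[j]) for r in rows) for j in range(len(header))]
    lines = ["  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip()
             for row in rows]
    return "\n".join(lines) + "\n"


def _summary_frame(summary: cl.ConfusionSummary) -> pd.DataFrame:
    rows = []
    for i, tc in enumerate(summary.classes):
        for j, pc in enumerate(summary.classes):
            rows.append({
                "true_class": tc, "predicted_class": pc,
                "mean_count": summary.mean_counts[i, j],
                "percent_of_row": summary.percent[i, j],
                "sigma": summary.sigma[i, j],
                "n_runs": summary.n_runs,
            })
    return pd.DataFrame(rows)


@dataclass
class RunReport:
    """Paths and headline numbers of one full pipeline run."""

    out_dir: Path
    files: dict[str, Path]
    k_star_bic: dict[str, int]  # per clustering method
    k_star_gap: dict[str, int]
    n_components_95: int
    scree_elbow: int
    accuracies: dict[str, dict[str, float]]
    warnings_count: int


def run_all(config: PipelineConfig) -> RunReport:
    """Execute the whole pipeline; deterministic given the master seed."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    n_warnings = 0

    def _stage(name):
        log.info("stage %s", name)

    # 1 — simulate
    _stage("simulate")
    grid = config.build_grid()
    refs = synth.default_references(grid)
    samples = synth.simulate_dataset(
        config.build_dataset_spec(), config.build_class_params(), grid=grid, refs=refs
    )
    manifest = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "patient_id": [s.patient_id for s in samples],
            "true_class": [s.true_class for s in samples],
        }
    )
    files["manifest"] = out / "manifest.csv"
    manifest.to_csv(files["manifest"], index=False)
    if config.write_raw_frames:
        from .io import write_dataset

        write_dataset(samples, out / "raw")

    # 2 — preprocess
    _stage("preprocess")
    fm = preprocess.build_feature_matrix(samples, config.energy)
    files["features"] = out / "features_full.csv"
    fm.to_dataframe().to_csv(files["features"])

    # 3 — model-order study (Fig.-2-style: BIC and gap for K-means and GMM)
    _stage("model_order")
    seed_mo = derive_seed(config.master_seed, "model_order")
    emb = None
    if config.model_order_space == "pca":
        X_mo = dimred.pca_fit(fm.values, n_components=config.dim).scores
    elif config.model_order_space == "tsne":
        emb = dimred.tsne_embed(fm.values, d=config.dim, perplexity=config.perplexity,
                                seed=derive_seed(config.master_seed, "embed"))
        X_mo = emb.coords
    elif config.model_order_space == "full":
        X_mo = fm.values
    else:
        raise ValueError(f"unknown model_order_space {config.model_order_space!r}")
    k_rng = range(config.k_min, config.k_max + 1)
    mo_frames = []
    k_star_bic: dict[str, int] = {}
    k_star_gap: dict[str, int] = {}
    mo_results = {}
    for method in ("kmeans", "gmm"):
        bic_res = cl.bic_curve(X_mo, k_rng, method=method, seed=seed_mo)
        gap_res = cl.gap_statistic(X_mo, k_rng, B=config.gap_B, method=method,
                                   seed=seed_mo, rule=config.gap_rule)
        k_star_bic[method] = bic_res.k_star_bic
        k_star_gap[method] = gap_res.k_star_gap
        mo_results[method] = (bic_res, gap_res)
        mo_frames.append(pd.DataFrame({
            "method": method, "k": bic_res.k_range, "bic": bic_res.bic,
            "gap": gap_res.gap, "s_k": gap_res.s_k,
        }))
    files["model_order"] = out / "model_order.csv"
    pd.concat(mo_frames).to_csv(files["model_order"], index=False)
    if config.k == "auto":
        k = k_star_gap[config.cluster_method]
    else:
        k = int(config.k)

    # 4 — PCA study
    _stage("pca")
    pca = dimred.pca_fit(fm.values)
    m95 = dimred.n_components_cumvar(pca, 0.95)
    elbow = dimred.scree_elbow(pca.explained_variance)
    centers = tuple(sorted(c.center_nm for c in samples[0].channels))
    comps = dimred.components_in_spectral_space(pca, min(6, pca.components.shape[0]),
                                               grid, centers)
    files["pca_variance"] = out / "pca_variance.csv"
    pd.DataFrame({
        "component": np.arange(1, pca.explained_variance_ratio.size + 1),
        "explained_variance": pca.explained_variance,
        "explained_variance_ratio": pca.explained_variance_ratio,
        "cumulative_ratio": np.cumsum(pca.explained_variance_ratio),
    }).to_csv(files["pca_variance"], index=False)
    files["pca_peaks"] = out / "pca_component_peaks.csv"
    pd.DataFrame([
        {"component": c.index, "channel_nm": ch, "peak_nm": c.peak_nm[ch]}
        for c in comps for ch in centers
    ]).to_csv(files["pca_peaks"], index=False)

    # 5 — repeated clustering (Table-1-style summary)
    _stage("repeated_clustering")
    base = derive_seed(config.master_seed, "runs")
    runs, _seeds = expert._protocol_runs(fm.values, k, config.n_runs, base,
                                         config.dim, config.perplexity, 10)
    present = tuple(c for c in synth.CLASS_ORDER if c in set(fm.true_classes))
    summary = cl.confusion_summary(runs, fm.true_classes, classes=present)
    files["confusion"] = out / "confusion_ml.csv"
    _summary_frame(summary).to_csv(files["confusion"], index=False)
    files["confusion_table"] = out / "confusion_ml.txt"
    files["confusion_table"].write_text(render_table(summary))

    # 6 — expert comparison
    _stage("expert_comparison")
    comparison = expert.compare_pipelines(
        samples, refs, k=k, n_runs=config.n_runs, dim=config.dim,
        perplexity=config.perplexity,
        base_seed=derive_seed(config.master_seed, "compare"),
        energy=config.energy, window=config.build_window(),
    )
    files["comparison"] = out / "comparison.csv"
    pd.concat([
        _summary_frame(comparison.ml).assign(arm="ml"),
        _summary_frame(comparison.expert).assign(arm="expert"),
    ]).to_csv(files["comparison"], index=False)
    files["comparison_table"] = out / "comparison.txt"
    files["comparison_table"].write_text(
        "ML model\n" + render_table(comparison.ml)
        + "\nExpert model\n" + render_table(comparison.expert)
    )
    files["accuracies"] = out / "accuracies.json"
    files["accuracies"].write_text(json.dumps(comparison.accuracies, indent=1))

    if config.make_plots:
        bic_res, gap_res = mo_results[config.cluster_method]
        _make_plots(out, files, bic_res, gap_res, pca, comps, emb=emb, grid=grid,
                    true_classes=fm.true_classes)

    # resolved config + checksum manifest
    files["config"] = out / "config.yaml"
    config.to_yaml(files["config"])
    checksums = {
        name: hashlib.sha256(path.read_bytes()).hexdigest()
        for name, path in sorted(files.items())
    }
    run_manifest = out / "run_manifest.json"
    run_manifest.write_text(json.dumps(
        {name: {"path": str(files[name].relative_to(out)), "sha256": checksums[name]}
         for name in sorted(files)}, indent=1))
    files["run_manifest"] = run_manifest

    return RunReport(
        out_dir=out,
        files=files,
        k_star_bic=k_star_bic,
        k_star_gap=k_star_gap,
        n_components_95=m95,
        scree_elbow=elbow,
        accuracies=comparison.accuracies,
        warnings_count=n_warnings,
    )


def _make_plots(out, files, bic_res, gap_res, pca, comps, emb, grid, true_classes):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    axes[0].plot(bic_res.k_range, bic_res.bic, "o-")
    axes[0].axvline(bic_res.k_star_bic, color="r", ls="-.")
    axes[0].set(xlabel="number of clusters", ylabel="BIC")
    axes[1].errorbar(gap_res.k_range, gap_res.gap, yerr=gap_res.s_k, fmt="o-")
    axes[1].axvline(gap_res.k_star_gap, color="r", ls="-.")
    axes[1].set(xlabel="number of clusters", ylabel="gap")
    fig.tight_layout()
    files["plot_model_order"] = out / "model_order.png"
    fig.savefig(files["plot_model_order"], dpi=110)
    plt.close(fig)

    ratios = pca.explained_variance_ratio
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    upto = min(15, ratios.size)
    axes[0].plot(np.arange(1, upto + 1), pca.explained_variance[:upto], "o-")
    axes[0].set(xlabel="component", ylabel="eigenvalue", title="scree")
    axes[1].plot(np.arange(1, upto + 1), np.cumsum(ratios)[:upto], "o-")
    axes[1].axhline(0.95, color="r", ls=":")
    axes[1].set(xlabel="component", ylabel="cumulative variance")
    fig.tight_layout()
    files["plot_pca"] = out / "pca_variance.png"
    fig.savefig(files["plot_pca"], dpi=110)
    plt.close(fig)

    fig, axes = plt.subplots(len(comps), 1, figsize=(6, 1.8 * len(comps)),
                             sharex=True, squeeze=False)
    ch = sorted(comps[0].blocks)[1] if len(comps[0].blocks) > 1 else sorted(comps[0].blocks)[0]
    for ax, comp in zip(axes[:, 0], comps):
        block = comp.normalized_blocks()[ch]
        ax.plot(grid.values, block)
        ax.axvline(comp.peak_nm[ch], color="r", ls=":")
        ax.set_ylabel(f"PC{comp.index}")
    axes[-1, 0].set_xlabel("emission wavelength (nm)")
    fig.tight_layout()
    files["plot_components"] = out / "pca_components.png"
    fig.savefig(files["plot_components"], dpi=110)
    plt.close(fig)

    if emb is not None:
        fig = plt.figure(figsize=(5, 4))
        ax = fig.add_subplot(projection="3d" if emb.coords.shape[1] == 3 else None)
        classes = sorted(set(true_classes), key=list(synth.CLASS_ORDER).index)
        for c in classes:
            idx = [i for i, t in enumerate(true_classes) if t == c]
            pts = emb.coords[idx]
            ax.scatter(*pts.T, label=c, s=18)
        ax.legend(fontsize=7)
        fig.tight_layout()
        files["plot_embedding"] = out / "embedding.png"
        fig.savefig(files["plot_embedding"], dpi=110)
        plt.close(fig)


# ---------------------------------------------------------------------------
# Named study conditions (used by the reproduction script and the test suite)
# ---------------------------------------------------------------------------

def gap_model_order_study(
    master_seed: int = 0,
    n_repeats: int = 20,
    k_range=range(1, 9),
    B: int = 50,
    dim: int = 3,
    perplexity: float = 10.0,
) -> tuple[int, list[int]]:
    """Gap-criterion cluster-count recovery on the default synthetic cohort.

    Simulates the default four-class 50-sample dataset, preprocesses it,
    and for each of ``n_repeats`` repetitions embeds to ``dim`` dimensions
    (t-SNE, seeded per repetition) and selects k by the gap-statistic argmax
    (K-means, uniform bounding-box reference).  Returns the modal selected k
    and the per-repetition selections.
    """
    spec = synth.DatasetSpec(seed=derive_seed(master_seed, "simulate"))
    samples = synth.simulate_dataset(spec)
    fm = preprocess.build_feature_matrix(samples)
    base = derive_seed(master_seed, "model_order")
    picks = []
    for i in range(n_repeats):
        emb = dimred.tsne_embed(fm.values, d=dim, perplexity=perplexity, seed=base + i)
        res = cl.gap_statistic(emb.coords, k_range, B=B, method="kmeans",
                               seed=base + 1000 + i)
        picks.append(res.k_star_gap)
    values, counts = np.unique(picks, return_counts=True)
    modal = int(values[int(np.argmax(counts))])
    return modal, picks


def component_count_study(seed: int = 0, n_samples: int = 50,
                          threshold: float = 0.95) -> int:
    """Components needed for 95% cumulative variance on five-component
    synthetic mixtures (comparably-weighted bases, 1% noise)."""
    X, _bases = synth.simulate_component_mixtures(n_samples=n_samples, seed=seed)
    pca = dimred.pca_fit(X)
    return dimred.n_components_cumvar(pca, threshold)
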