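"""End-to-end orchestration: ingest -> profile -> embed -> cluster -> regional.

`run_pipeline` executes the five analysis stages on either the three
PUF-shaped input tables or a synthetic population, writes every artifact as
delimited text under an output directory, and records a JSON-lines manifest
(one record per stage: status, parameters, seed, output files).  All
randomness flows from the single global seed in the config; rerunning the
same config reproduces every deterministic artifact byte-for-byte.

`render_figures` turns the written artifacts into the standard figure set:
embedding density heatmaps, per-specialty highlight grids, single-feature
fraction overlays (color capped at 15% of a provider's claims), pairwise
region log-log scatter with fold bands, and the regional MDS scatter with
its permutation cloud.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, embedding, io, profiles, regional, synthetic
from .errors import RxscapeError, ValidationError

STAGES = ("ingest", "profile", "embed", "cluster", "regional")


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run.

    Either ``provider_file``/``drug_file``/``link_file`` point at PUF-shaped
    tables, or ``simulation`` holds a :class:`SimulationConfig` and the
    inputs are generated.  ``seed`` feeds every stochastic stage through
    derived child seeds.
    """

    out_dir: Path
    provider_file: Path | None = None
    drug_file: Path | None = None
    link_file: Path | None = None
    simulation: synthetic.SimulationConfig | None = None
    censor_threshold: int = 11
    min_claims: int = 0
    feature_level: str = "drugs"
    embedding_config: embedding.EmbeddingConfig | None = None
    n_clusters: int = 20
    n_perm: int = 100
    min_national_claims: int = 0
    region_col: str = "cbsa"
    seed: int = 0

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        have_files = all(
            p is not None for p in (self.provider_file, self.drug_file, self.link_file)
        )
        if not have_files and self.simulation is None:
            raise ValidationError(
                "config needs either the three input tables or a simulation"
            )
        if self.feature_level not in ("drugs", "classes"):
            raise ValidationError("feature_level must be 'drugs' or 'classes'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load a config from a YAML file (keys mirror the dataclass fields)."""
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulation", None)
        emb = raw.pop("embedding", None)
        cfg = dict(raw)
        if sim is not None:
            cfg["simulation"] = synthetic.default_config(**sim)
        if emb is not None:
            cfg["embedding_config"] = embedding.EmbeddingConfig(**emb)
        return cls(**cfg)


def _child_seed(seed: int, stage: str) -> int:
    return int(
        np.random.SeedSequence([seed, STAGES.index(stage)]).generate_state(1)[0]
        % (2**31)
    )


def run_pipeline(config: PipelineConfig) -> list[dict]:
    """Run all stages, writing artifacts and a JSON-lines manifest.

    Returns the manifest: one record per stage with ``status`` of
    ``complete``, ``failed`` (the error message is recorded) or ``skipped``
    (an earlier stage failed).
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    failed = False
    state: dict = {}

    def record(stage: str, status: str, params: dict, outputs: list, error=None):
        rec = {
            "stage": stage,
            "status": status,
            "params": params,
            "outputs": [str(p) for p in outputs],
        }
        if error is not None:
            rec["error"] = str(error)
        manifest.append(rec)

    def stage(name: str, params: dict, fn):
        nonlocal failed
        if failed:
            record(name, "skipped", params, [])
            return
        try:
            outputs = fn()
            record(name, "complete", params, outputs)
        except RxscapeError as exc:
            failed = True
            record(name, "failed", params, [], error=exc)

    # ingest -----------------------------------------------------------
    def do_ingest():
        if config.simulation is not None:
            matrix, ann, class_map, truth = synthetic.generate_population(
                config.simulation
            )
            state["truth"] = truth
        else:
            matrix, ann = io.read_puf(
                config.provider_file, config.drug_file, config.link_file
            )
            matrix = io.apply_censoring(matrix, config.censor_threshold)
            class_map = None
        matrix, report = io.drop_empty(matrix)
        ann = ann.loc[matrix.providers]
        state.update(matrix=matrix, annotations=ann, class_map=class_map,
                     drop_report=report)
        paths = io.write_puf_tables(matrix, ann, out / "ingest")
        return list(paths.values())

    stage(
        "ingest",
        {"censor_threshold": config.censor_threshold,
         "simulated": config.simulation is not None},
        do_ingest,
    )

    # profile ----------------------------------------------------------
    def do_profile():
        prof = profiles.build_profiles(
            state["matrix"],
            feature_level=config.feature_level,
            class_map=state["class_map"],
            normalize=True,
        )
        prof = profiles.filter_min_claims(prof, config.min_claims)
        if prof.shape[0] == 0:
            raise ValidationError(
                f"min_claims={config.min_claims} excludes every provider"
            )
        state["profile"] = prof
        prov_stats, feat_stats = profiles.diversity_volume(state["matrix"])
        p1 = out / "provider_stats.csv"
        p2 = out / "feature_stats.csv"
        prov_stats.to_csv(p1)
        feat_stats.to_csv(p2)
        g = profiles.gini(
            feat_stats["total_claims"].to_numpy(),
            seed=_child_seed(config.seed, "profile"),
        )
        p3 = out / "gini.json"
        p3.write_text(json.dumps(g.__dict__, indent=2))
        return [p1, p2, p3]

    stage("profile", {"min_claims": config.min_claims,
                      "feature_level": config.feature_level}, do_profile)

    # embed ------------------------------------------------------------
    def do_embed():
        emb_cfg = config.embedding_config or embedding.EmbeddingConfig(
            seed=_child_seed(config.seed, "embed")
        )
        prof = state["profile"]
        reduced = embedding.pca_reduce(prof, emb_cfg.pca_dims)
        emb = embedding.tsne_embed(reduced, emb_cfg, providers=prof.providers)
        state["embedding"] = emb
        p = out / "embedding.csv"
        df = emb.to_frame()
        df["cost_run"] = emb.cost
        df.to_csv(p)
        return [p]

    stage("embed", {"seed": _child_seed(config.seed, "embed")}, do_embed)

    # cluster ----------------------------------------------------------
    def do_cluster():
        assign = clustering.ward_cluster(state["profile"], n_clusters=config.n_clusters)
        dom = clustering.cluster_dominance(assign, state["annotations"])
        state["clusters"] = assign
        p1 = out / "clusters.csv"
        assign.labels.to_csv(p1)
        p2 = out / "dominance.csv"
        dom.per_cluster.to_csv(p2)
        return [p1, p2]

    stage("cluster", {"n_clusters": config.n_clusters}, do_cluster)

    # regional ---------------------------------------------------------
    def do_regional():
        ann = state["annotations"]
        enrollees = (
            synthetic.make_enrollee_table(config.simulation)
            .set_index("region")["enrollees"]
            if config.simulation is not None
            else ann.groupby(config.region_col).size() * 100.0
        )
        prof = regional.region_profiles(
            state["matrix"], ann, enrollees,
            region_col=config.region_col,
            min_national_claims=config.min_national_claims,
        )
        state["region_profiles"] = prof
        null = regional.permutation_null(
            state["matrix"], ann, enrollees,
            n_perm=config.n_perm,
            seed=_child_seed(config.seed, "regional"),
            region_col=config.region_col,
            min_national_claims=config.min_national_claims,
        )
        state["null"] = null
        p1 = out / "region_profiles.csv"
        prof.to_frame().to_csv(p1)
        p2 = out / "mds.csv"
        pd.DataFrame(null.real_coords, index=null.regions,
                     columns=["x", "y"]).to_csv(p2)
        p3 = out / "permutation_null.json"
        p3.write_text(json.dumps({
            "real_dispersion": null.real_dispersion,
            "permuted_dispersions": null.permuted_dispersions.tolist(),
        }, indent=2))
        return [p1, p2, p3]

    stage("regional", {"n_perm": config.n_perm,
                       "min_national_claims": config.min_national_claims},
          do_regional)

    manifest_path = out / "manifest.jsonl"
    with open(manifest_path, "w") as fh:
        for rec in manifest:
            fh.write(json.dumps(rec) + "\n")
    state["manifest_path"] = manifest_path
    run_pipeline.last_state = state  # kept for render_figures convenience
    return manifest


run_pipeline.last_state = {}


def render_figures(
    config: PipelineConfig,
    which: list[str] | None = None,
    state: dict | None = None,
) -> list[Path]:
    """Render figures from a completed run's in-memory state.

    ``which`` selects from ``density``, ``specialty_grid``,
    ``fraction_overlay``, ``region_pair``, ``mds`` (default: all that have
    their upstream artifacts available).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    state = state or run_pipeline.last_state
    which = which or ["density", "specialty_grid", "fraction_overlay",
                      "region_pair", "mds"]
    out = Path(config.out_dir) / "figures"
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def need(*keys):
        missing = [k for k in keys if k not in state]
        if missing:
            raise ValidationError(
                f"missing upstream artifact(s) {missing}; rerun that stage"
            )

    if "density" in which:
        need("embedding")
        hist, xe, ye = embedding.density_map(state["embedding"], bins=60)
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.pcolormesh(xe, ye, hist.T, cmap="Greys")
        ax.set_title("Provider density in the embedding")
        p = out / "density.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

    if "specialty_grid" in which:
        need("embedding", "annotations")
        emb = state["embedding"]
        spec = state["annotations"]["specialty"].reindex(emb.providers)
        names = sorted(spec.dropna().unique())
        ncol = min(3, len(names))
        nrow = int(np.ceil(len(names) / ncol))
        fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 3 * nrow),
                                 squeeze=False)
        for ax, name in zip(axes.ravel(), names):
            ax.scatter(*emb.coords.T, s=2, c="lightgray")
            mask = (spec == name).to_numpy()
            ax.scatter(*emb.coords[mask].T, s=3, c="red")
            ax.set_title(name, fontsize=8)
            ax.set_xticks([]), ax.set_yticks([])
        for ax in axes.ravel()[len(names):]:
            ax.axis("off")
        p = out / "specialty_grid.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

    if "fraction_overlay" in which:
        need("embedding", "matrix")
        emb = state["embedding"]
        matrix = state["matrix"]
        feature = matrix.drugs[int(np.argmax(matrix.column_totals()))]
        sub = matrix.providers.get_indexer(emb.providers)
        vals, _ = embedding.annotate_fraction(matrix, feature, cap=15.0)
        fig, ax = plt.subplots(figsize=(5, 5))
        sc = ax.scatter(*emb.coords.T, s=4, c=vals[sub], cmap="Reds",
                        vmin=0.0, vmax=15.0)
        fig.colorbar(sc, label="% of provider claims (capped at 15%)")
        ax.set_title(f"Claim fraction: {feature[0]}")
        p = out / "fraction_overlay.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

    if "region_pair" in which:
        need("region_profiles")
        prof = state["region_profiles"]
        if len(prof.regions) >= 2:
            a, b = prof.regions[0], prof.regions[1]
            cmp_df = regional.pairwise_region_compare(prof, a, b, fold=5.0)
            fig, ax = plt.subplots(figsize=(5, 5))
            ax.scatter(cmp_df["rate_a"], cmp_df["rate_b"], s=8)
            lims = (max(cmp_df[["rate_a", "rate_b"]].min().min(), 1e-9),
                    cmp_df[["rate_a", "rate_b"]].max().max())
            grid = np.geomspace(*lims, 50)
            ax.plot(grid, grid, "k-", lw=0.5)
            ax.plot(grid, 5.0 * grid, "k--", lw=0.5)
            ax.plot(grid, grid / 5.0, "k--", lw=0.5)
            ax.set_xscale("log"), ax.set_yscale("log")
            ax.set_xlabel(f"{a} claims/enrollee"), ax.set_ylabel(f"{b} claims/enrollee")
            ax.set_title("5-fold difference bands (dashed)")
            p = out / "region_pair.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written.append(p)

    if "mds" in which:
        need("null")
        null = state["null"]
        fig, ax = plt.subplots(figsize=(5, 5))
        cloud = null.permuted_coords.reshape(-1, 2)
        ax.scatter(*cloud.T, s=4, c="magenta", alpha=0.3,
                   label="permutation null")
        ax.scatter(*null.real_coords.T, s=25, c="black", label="regions")
        for (x, y), name in zip(null.real_coords, null.regions):
            ax.annotate(name, (x, y), fontsize=7)
        ax.legend(fontsize=7)
        ax.set_title("Regional MDS with permutation null")
        p = out / "mds.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

    return written
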