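"""End-to-end analysis runner: preprocess -> reduce -> PLS -> inference ->
generalize -> gradients -> spatial contextualization.

Mirrors the canonical workflow for multi-site brain-behavior latent
component studies: confound residualization, matched discovery/replication
split, per-modality PCA, PLS correlation in the discovery arm with
site-restricted permutation and bootstrap inference, out-of-sample weight
transfer, diffusion-map gradients from the full-sample mean connectivity,
and spin-permutation contextualization of cortical loading maps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import MultimodalDataset, NetworkPartition, ParcelSphereCoords
from .generalize import (
    demographic_posthoc,
    fit_transfer,
    transfer_scores,
    transfer_significance,
)
from .gradients import build_affinity, diffusion_embed, procrustes_align
from .inference import (
    BootstrapTarget,
    block_labels,
    bootstrap_loadings,
    permutation_test,
)
from .io import write_json, write_partition, write_centroids, write_table
from .pls import modality_contribution, pls_decompose, project_loadings_back
from .preprocess import (
    build_design,
    drop_invariant_items,
    matched_split,
    modality_covariates,
    overall_psychopathology,
    residualize,
)
from .reduction import fit_reduction
from .spatial import gradient_contextualize, parcelwise_network_loadings, spin_permutation
from .synth import SyntheticConfig, generate_dataset, generate_parcellation_assets
from .utils import devectorize_edges

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end analysis, with study-scale defaults."""

    synthetic: SyntheticConfig | None = None
    variance_threshold: float = 0.5
    n_perm: int = 10_000
    n_boot: int = 1000
    n_spin: int = 1000
    k_test: int = 5
    q: float = 0.05
    split_fraction: float = 2.0 / 3.0
    n_networks: int | None = None  # default: 17 cortical + 1 subcortical
    n_gradients: int = 10
    gradient_top_fraction: float = 0.10
    alpha: float = 0.5
    diffusion_time: float = 0.0
    seed: int = 0
    include_volume: bool = True
    include_ethnicity_covariate: bool = True
    standardize_pca: bool = False
    absolute_network_loadings: bool = False
    residualize_scope: str = "full"  # "full" or "discovery"
    procrustes_reference: str | None = None  # path to a reference-gradient TSV

    def validate(self) -> None:
        if not 0 < self.variance_threshold <= 1:
            raise ValueError("variance_threshold must be in (0, 1]")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.residualize_scope not in ("full", "discovery"):
            raise ValueError("residualize_scope must be 'full' or 'discovery'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"]["item_thresholds"] = np.asarray(
                self.synthetic.item_thresholds
            ).tolist()
        return d


def _terms_for(modality: str, include_ethnicity: bool) -> list[str]:
    terms = modality_covariates(modality)
    if not include_ethnicity:
        terms = [t for t in terms if t != "ethnicity"]
    return terms


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    dataset: MultimodalDataset | None = None,
    partition: NetworkPartition | None = None,
    coords: ParcelSphereCoords | None = None,
) -> dict:
    """Execute the full workflow; returns a dict of in-memory results.

    Inputs come either from ``config.synthetic`` or from pre-built tables
    passed directly. All artifacts are written under ``outdir`` and listed
    in ``manifest.json`` together with the config hash and seeds; re-running
    with the same config reproduces all outputs (fixed seeds throughout).
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    results: dict = {}

    def emit(name, df, index_label=None):
        write_table(df, outdir / name, index_label=index_label)
        outputs.append(name)

    # ------------------------------------------------------------------ data
    stage = "data"
    try:
        if dataset is None:
            if config.synthetic is None:
                raise ValueError("either a dataset or config.synthetic is required")
            dataset, truth = generate_dataset(config.synthetic)
            results["truth"] = truth
        if partition is None or coords is None:
            if config.synthetic is None:
                raise ValueError("partition and coords are required with a user dataset")
            partition, coords = generate_parcellation_assets(
                config.synthetic, config.n_networks
            )
        if not config.include_volume:
            dataset = MultimodalDataset(
                modality_blocks={m: b for m, b in dataset.modality_blocks.items()
                                 if m != "volume"},
                behavior=dataset.behavior,
                covariates=dataset.covariates,
            )
        site = dataset.covariates["site"].to_numpy()
        n_parcels = len(partition.labels)

        # -------------------------------------------------------- preprocess
        stage = "preprocess"
        psy = overall_psychopathology(dataset.behavior)
        split = matched_split(dataset.covariates, psy, config.split_fraction,
                              seed=config.seed)
        emit("balance_report.tsv", split.balance_report.set_index("variable"))
        behavior_kept, dropped_items = drop_invariant_items(
            dataset.behavior, split.discovery_idx
        )
        log.info("split %d/%d; dropped items: %s", len(split.discovery_idx),
                 len(split.replication_idx), dropped_items)

        def residualized(scope_idx=None):
            cov = dataset.covariates if scope_idx is None else dataset.covariates.iloc[scope_idx]
            blocks = {}
            for m, b in dataset.modality_blocks.items():
                bb = b if scope_idx is None else b.iloc[scope_idx]
                blocks[m] = residualize(bb, cov, _terms_for(m, config.include_ethnicity_covariate))
            bk = behavior_kept if scope_idx is None else behavior_kept.iloc[scope_idx]
            beh = residualize(bk.astype(float), cov,
                              _terms_for("behavior", config.include_ethnicity_covariate))
            return blocks, beh

        if config.residualize_scope == "full":
            blocks_r, behavior_r = residualized()
            disc_blocks = {m: b.iloc[split.discovery_idx] for m, b in blocks_r.items()}
            disc_behavior = behavior_r.iloc[split.discovery_idx]
            repl_blocks = {m: b.iloc[split.replication_idx] for m, b in blocks_r.items()}
            repl_behavior = behavior_r.iloc[split.replication_idx]
        else:
            disc_blocks, disc_behavior = residualized(split.discovery_idx)
            repl_blocks, repl_behavior = residualized(split.replication_idx)

        # ------------------------------------------------------------ reduce
        stage = "reduce"
        reduction, X_disc = fit_reduction(
            disc_blocks, config.variance_threshold, config.standardize_pca
        )
        log.info("retained components per modality: %s", reduction.retained_counts)
        reduction.save(outdir / "reduction_model")
        outputs.append("reduction_model/reduction.json")

        # --------------------------------------------------------------- pls
        stage = "pls"
        result = pls_decompose(X_disc, disc_behavior)
        k_test = min(config.k_test, result.n_components)
        emit("composite_scores.tsv", pd.DataFrame(
            np.hstack([result.LX[:, :k_test], result.LY[:, :k_test]]),
            index=X_disc.scores.index,
            columns=[f"LX{k+1}" for k in range(k_test)] + [f"LY{k+1}" for k in range(k_test)],
        ))
        emit("behavior_loadings.tsv", pd.DataFrame(
            result.behavior_loadings[:, :k_test],
            index=disc_behavior.columns,
            columns=[f"LC{k+1}" for k in range(k_test)],
        ), index_label="item")
        loading_maps = project_loadings_back(result, disc_blocks)
        for m in disc_blocks:
            emit(f"imaging_loadings_{m}.tsv", pd.DataFrame(
                loading_maps[m][:, :k_test],
                index=disc_blocks[m].columns,
                columns=[f"LC{k+1}" for k in range(k_test)],
            ), index_label="feature")
        contributions = {m: modality_contribution(result, X_disc, m)[:k_test].tolist()
                         for m in reduction.order}

        # --------------------------------------------------------- inference
        stage = "inference"
        site_disc = site[split.discovery_idx]
        beh_design = build_design(
            dataset.covariates.iloc[split.discovery_idx],
            _terms_for("behavior", config.include_ethnicity_covariate),
        ).to_numpy()
        perm = permutation_test(X_disc, disc_behavior, site_disc, config.n_perm,
                                k_test, seed=config.seed + 1, design=beh_design)
        emit("permutation_null.tsv", pd.DataFrame(
            perm.null_distribution, columns=[f"LC{k+1}" for k in range(k_test)]
        ))
        rsfc_edges = disc_blocks["rsfc"].to_numpy()
        targets = {
            "rsfc_blocks": BootstrapTarget(
                rsfc_edges, composite="LX", partition=partition,
                parcel_order=partition.labels.index,
            )
        }
        boot = bootstrap_loadings(X_disc, disc_behavior, site_disc, config.n_boot,
                                  targets, seed=config.seed + 2, q=config.q)
        for name in ("behavior", "rsfc_blocks"):
            labels = (list(disc_behavior.columns) if name == "behavior"
                      else block_labels(partition))
            emit(f"bootstrap_summary_{name}.tsv", pd.DataFrame({
                "target": np.repeat(labels, boot.loadings[name].shape[1]),
                "component": np.tile(np.arange(1, boot.loadings[name].shape[1] + 1),
                                     len(labels)),
                "loading": boot.loadings[name].ravel(),
                "sd": boot.loading_sd[name].ravel(),
                "z": boot.z_scores[name].ravel(),
                "p": boot.p_values[name].ravel(),
                "significant": boot.fdr_mask[name].ravel(),
                "ci_lo": boot.ci_low[name].ravel(),
                "ci_hi": boot.ci_high[name].ravel(),
            }).set_index("target"))

        # --------------------------------------------------------- gradients
        stage = "gradients"
        mean_conn = devectorize_edges(
            dataset.modality_blocks["rsfc"].to_numpy().mean(0), n_parcels, diag=1.0
        )
        affinity = build_affinity(mean_conn, config.gradient_top_fraction)
        grad = diffusion_embed(affinity, config.alpha, config.diffusion_time,
                               config.n_gradients)
        if config.procrustes_reference:
            ref = pd.read_csv(config.procrustes_reference, sep="\t", index_col=0)
            grad = procrustes_align(grad, ref.to_numpy(float),
                                    reference_id=str(config.procrustes_reference))
        emit("gradients.tsv", pd.DataFrame(
            grad.embedding, index=partition.labels.index,
            columns=[f"g{j+1}" for j in range(grad.embedding.shape[1])],
        ), index_label="parcel_id")
        write_json({"eigenvalues": grad.eigenvalues,
                    "variance_explained": grad.variance_explained},
                   outdir / "spectrum.json")
        outputs.append("spectrum.json")

        # ----------------------------------------------------------- spatial
        stage = "spatial"
        cortical_mask = coords.hemisphere.isin(["L", "R"]).to_numpy()
        spins = spin_permutation(coords, config.n_spin, seed=config.seed + 3)
        g1 = grad.embedding[cortical_mask, 0]
        maps = {}
        for m in disc_blocks:
            if m == "rsfc":
                continue
            for k in range(k_test):
                maps[f"{m}_LC{k+1}"] = loading_maps[m][:, k]
        for k in range(k_test):
            edge_mat = devectorize_edges(loading_maps["rsfc"][:, k], n_parcels)
            within, between = parcelwise_network_loadings(
                edge_mat, partition, absolute=config.absolute_network_loadings
            )
            maps[f"rsfc_within_LC{k+1}"] = within[cortical_mask]
            maps[f"rsfc_between_LC{k+1}"] = between[cortical_mask]
        spatial_table = gradient_contextualize(maps, g1, spins, q=config.q)
        emit("gradient_context.tsv", spatial_table.set_index("target"))

        # -------------------------------------------------------- generalize
        stage = "generalize"
        model = fit_transfer(reduction, X_disc.to_numpy(), disc_behavior)
        transfer = transfer_scores(model, repl_blocks, repl_behavior)
        obs_r, p_t, q_t = transfer_significance(
            model, repl_blocks, repl_behavior, site[split.replication_idx],
            n_perm=config.n_perm, k_test=k_test, seed=config.seed + 4,
        )
        repl_behavior_kept, _ = drop_invariant_items(
            dataset.behavior.iloc[split.replication_idx]
        )
        repl_behavior_full = residualize(
            repl_behavior_kept.astype(float),
            dataset.covariates.iloc[split.replication_idx],
            _terms_for("behavior", config.include_ethnicity_covariate),
        )
        _, X_repl = fit_reduction(repl_blocks, config.variance_threshold,
                                  config.standardize_pca)
        repl_result = pls_decompose(X_repl, repl_behavior_full)
        repl_maps = project_loadings_back(repl_result, repl_blocks)
        # compare on the items both arms retained
        shared = [c for c in disc_behavior.columns if c in repl_behavior_full.columns]
        di = [list(disc_behavior.columns).index(c) for c in shared]
        ri = [list(repl_behavior_full.columns).index(c) for c in shared]
        k_common = min(k_test, repl_result.n_components)
        cw_rows = []
        for comp in range(k_common):
            r = float(np.corrcoef(result.behavior_loadings[di, comp],
                                  repl_result.behavior_loadings[ri, comp])[0, 1])
            cw_rows.append(("behavior", comp + 1, r))
            for m in disc_blocks:
                r = float(np.corrcoef(loading_maps[m][:, comp],
                                      repl_maps[m][:, comp])[0, 1])
                cw_rows.append((m, comp + 1, r))
        crosswalk = pd.DataFrame(cw_rows, columns=["block", "component", "r"])
        emit("replication_crosswalk.tsv", crosswalk.set_index("block"))

        scores_df = pd.DataFrame(
            np.hstack([result.LX[:, :k_test], result.LY[:, :k_test]]),
            index=X_disc.scores.index,
            columns=[f"LX{k+1}" for k in range(k_test)] + [f"LY{k+1}" for k in range(k_test)],
        )
        posthoc = demographic_posthoc(
            scores_df, dataset.covariates.iloc[split.discovery_idx], q=config.q
        )
        emit("demographic_posthoc.tsv", posthoc.set_index("score"))

        within_r = result.lc_correlations[:k_test]
        write_json({
            "within_sample_r": within_r,
            "out_of_sample_r": obs_r,
            "p": p_t,
            "q": q_t,
            "dropped_items_replication": transfer.dropped_items,
        }, outdir / "transfer_report.json")
        outputs.append("transfer_report.json")

        # ----------------------------------------------------------- summary
        summary = {
            "n_subjects": dataset.n_subjects,
            "n_discovery": int(len(split.discovery_idx)),
            "n_replication": int(len(split.replication_idx)),
            "dropped_items_discovery": dropped_items,
            "retained_components": reduction.retained_counts,
            "singular_values": result.singular_values[:k_test],
            "covariance_explained": result.covariance_explained[:k_test],
            "lc_correlations": within_r,
            "permutation_p": perm.p_values,
            "permutation_q": perm.fdr_q,
            "modality_contributions": contributions,
            "gradient_variance_explained": grad.variance_explained,
        }
        write_json(summary, outdir / "summary.json")
        outputs.append("summary.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    write_partition(partition, outdir / "network_partition.tsv")
    write_centroids(coords, outdir / "parcel_centroids.tsv")
    outputs += ["network_partition.tsv", "parcel_centroids.tsv"]

    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "outputs": sorted(set(outputs)),
    }
    write_json(manifest, outdir / "manifest.json")

    results.update({
        "dataset": dataset,
        "split": split,
        "reduction": reduction,
        "pls": result,
        "permutation": perm,
        "bootstrap": boot,
        "gradients": grad,
        "spatial": spatial_table,
        "transfer": transfer,
        "transfer_p": (obs_r, p_t, q_t),
        "replication_pls": repl_result,
        "crosswalk": crosswalk,
        "posthoc": posthoc,
        "summary": summary,
    })
    return results
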