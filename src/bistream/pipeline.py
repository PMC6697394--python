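"""End-to-end driver: preprocess a block and run every analysis stage."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import behavior as behavior_mod
from . import classify as classify_mod
from . import cluster as cluster_mod
from . import embedding as embedding_mod
from . import erbp as erbp_mod
from . import io as io_mod
from . import preprocess as pre
from .config import PipelineConfig
from .containers import LabeledEpochs, RecordingBlock

__all__ = ["PipelineResult", "run_pipeline"]

log = logging.getLogger(__name__)

ALL_STAGES = ("aep", "classify", "erbp", "embed", "behavior")


@dataclass
class PipelineResult:
    """Everything one block's analysis produced."""

    epochs: LabeledEpochs
    aep: cluster_mod.SiteStatMap | None = None
    classification: classify_mod.ClassificationResult | None = None
    erbp: cluster_mod.SiteStatMap | None = None
    embedding: embedding_mod.TrialEmbedding | None = None
    behavior: dict | None = None


def run_pipeline(
    config: PipelineConfig,
    block: RecordingBlock,
    stages: tuple[str, ...] = ALL_STAGES,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Preprocess ``block`` and run the requested analysis stages.

    Stage names: ``aep`` (cluster-mass permutation test with FDR),
    ``classify`` (feature-selection SVM), ``erbp`` (high-gamma band power
    cluster test), ``embed`` (2-s diffusion-map embedding and maintenance
    rank-sum), ``behavior`` (dominance-duration statistics).  When
    ``out_dir`` is given, TSV/JSON outputs (stamped with the config hash and
    seed) are written there.
    """
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}; valid: {ALL_STAGES}")
    if block.timeline is None:
        raise ValueError("block has no behavioral timeline; nothing can be labeled")
    if block.stim is None:
        raise ValueError("block has no stimulus timeline; trials cannot be cut")
    log.info("pipeline config %s seed %d", config.digest(), config.seed)

    b = pre.resample_to_1khz(block)
    b = pre.bandpass_lfp(b, band=config.band)
    b = pre.remove_narrowband(b, stopband=config.stopband, n_discard=config.n_discard)
    ep = pre.epoch_triplets(b, window=(0.0, 600.0, 0.0))
    ep = pre.reject_trials(ep, n_sd=config.reject_sd)
    ep = pre.label_and_filter(ep, block.timeline, rt=config.rt)
    result = PipelineResult(epochs=ep)

    if "aep" in stages:
        result.aep = cluster_mod.aep_cluster_test(
            ep,
            n_perm=config.n_perm,
            q=config.q_fdr,
            min_len=config.min_cluster_samples,
            alpha=config.alpha_point,
            seed=config.seed,
        )
    if "classify" in stages:
        ft = classify_mod.bin_features(ep, bin_ms=config.bin_ms)
        result.classification = classify_mod.run_classification(
            ft,
            n_rep=config.n_rep,
            seed=config.seed,
            train_frac=config.train_frac,
            prob_thresh=config.prob_thresh,
            c=config.svm_c,
        )
    if "erbp" in stages:
        ep_g = erbp_mod.erbp_epochs(
            block if block.fs == 1000 else pre.resample_to_1khz(block),
            rt=config.rt,
            reject_sd=config.reject_sd,
            gamma_band=config.gamma_band,
            smooth_band=config.smooth_band,
        )
        result.erbp = erbp_mod.erbp_cluster_test(
            ep_g,
            n_perm=config.n_perm,
            q=config.q_fdr,
            min_len=config.min_cluster_samples,
            alpha=config.alpha_point,
            seed=config.seed,
        )
    if "embed" in stages:
        ep2 = pre.epoch_triplets(b, window=config.embed_window)
        ep2 = pre.reject_trials(ep2, n_sd=config.reject_sd)
        ep2 = pre.label_and_filter(ep2, block.timeline, rt=config.rt)
        result.embedding = embedding_mod.embed_epochs(ep2, lam=config.lam)
    if "behavior" in stages:
        durs = behavior_mod.extract_durations(block.timeline)
        beh: dict = {"n_durations": int(durs.durations.size)}
        if durs.durations.size >= 10:
            shape, mean = behavior_mod.fit_gamma(durs.normalized())
            beh.update(gamma_shape=shape, gamma_mean=mean)
        for percept in (1, 2):
            sel = durs.percepts == percept
            if sel.any():
                beh[f"mean_duration_{percept}stream_s"] = float(
                    durs.durations[sel].mean()
                )
        result.behavior = beh

    if out_dir is not None:
        _write_outputs(Path(out_dir), config, result)
    return result


def _write_outputs(out: Path, config: PipelineConfig, res: PipelineResult) -> None:
    out.mkdir(parents=True, exist_ok=True)
    io_mod.write_epochs(out / "epochs.h5", res.epochs)
    report: dict = {}
    if res.aep is not None:
        io_mod.write_table(out / "aep_site_map.tsv", res.aep.table, config)
        report["aep_n_fdr_sites"] = int(res.aep.table["q_reject"].sum())
    if res.classification is not None:
        io_mod.write_table(out / "feature_probability.tsv", res.classification.feature_map(), config)
        report["classifier"] = {
            "mean_accuracy": res.classification.mean_accuracy,
            "median_accuracy": res.classification.median_accuracy,
            "selected_sites": res.classification.selected_sites(),
        }
    if res.erbp is not None:
        io_mod.write_table(out / "erbp_site_map.tsv", res.erbp.table, config)
        report["erbp_n_fdr_sites"] = int(res.erbp.table["q_reject"].sum())
    if res.embedding is not None:
        emb = res.embedding
        io_mod.write_table(
            out / "embedding.tsv",
            pd.DataFrame(
                {
                    "trial_onset_s": emb.trial_onsets,
                    "coord": emb.coord,
                    "label": emb.labels,
                }
            ),
            config,
        )
        report["embedding_eigenvalue"] = emb.eigenvalue
    if res.behavior is not None:
        report["behavior"] = res.behavior
    io_mod.write_report(out / "report.json", report, config)
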