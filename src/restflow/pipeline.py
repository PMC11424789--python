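"""End-to-end orchestration: cohort files -> features -> group statistics.

Stage order follows the analysis strategy: sensor conditioning (high-pass,
bad channels, artifact ICA, epoching) -> weighted minimum-norm inverse ->
region aggregation -> decimation to the analysis rate -> per-epoch MVAR +
PDC -> band averaging -> inflow/outflow and thresholded graph metrics at
the SOZ region -> rank-sum group comparison. Each stage is usable on its
own; `run_pipeline` ties them together over a patient manifest with a
continue-on-error contract.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from . import io as rio
from .graph import PatientFeatures, extract_soz_features, node_metrics, threshold_network
from .inverse import aggregate_regions, apply_inverse, compute_wmne_operator, RegionEpochs
from .io import PipelineConfig
from .mvar import fit_mvar_epochs
from .pdc import FrequencyBands, band_average, default_freq_grid, inflow_outflow, pdc_spectrum, BAND_ORDER
from .preproc import EpochSet, SensorRecording, detect_bad_channels, extract_epochs, highpass_filter, remove_artifact_components
from .stats import boxplot_summary, compare_groups, features_to_frame
from .synth import CohortDataset, LeadField

__all__ = [
    "preprocess_recording",
    "recording_to_region_epochs",
    "decimate_region_epochs",
    "connectivity_from_region_epochs",
    "features_for_patient",
    "cohort_features",
    "write_cohort",
    "run_pipeline",
]

log = logging.getLogger("restflow")


def _bands(config: PipelineConfig) -> FrequencyBands:
    return FrequencyBands(**{k: tuple(v) for k, v in config.bands.items()})


def preprocess_recording(rec: SensorRecording, config: PipelineConfig,
                         ) -> tuple[EpochSet, np.ndarray]:
    """Filter, drop bad channels, remove artifact components, epoch.

    Returns the epoch set (good channels only) and the indices of the good
    channels in the original channel order (needed to subset lead fields).
    """
    rec = highpass_filter(rec, config.highpass_hz)
    bad = detect_bad_channels(rec, config.bad_channel_z) if rec.n_channels >= 4 else set()
    rec.bad_channels |= bad
    if rec.artifact_refs is not None:
        rec = remove_artifact_components(
            rec, corr_thresh=config.ica_corr_thresh, seed=config.seed,
            max_components=config.ica_max_components,
        )
    good = rec.good_indices()
    sub = SensorRecording(
        data=rec.data[good], fs_hz=rec.fs_hz,
        channel_labels=[rec.channel_labels[i] for i in good],
        clean_mask=rec.clean_mask,
    )
    epochs = extract_epochs(sub, n_epochs=config.n_epochs,
                            epoch_len_s=config.epoch_s)
    return epochs, good


def recording_to_region_epochs(
    rec: SensorRecording,
    leadfield: LeadField,
    config: PipelineConfig,
) -> RegionEpochs:
    """Full sensor-to-region chain for one patient."""
    epochs, good = preprocess_recording(rec, config)
    lf_good = LeadField(gain=leadfield.gain[good],
                        source_region_map=leadfield.source_region_map,
                        source_signs=leadfield.source_signs)
    op = compute_wmne_operator(lf_good, lambda_reg=config.lambda_reg,
                               depth_gamma=config.depth_gamma)
    src = apply_inverse(epochs, op)
    return aggregate_regions(src, leadfield.source_region_map, fs_hz=rec.fs_hz)


def decimate_region_epochs(region_epochs: RegionEpochs, config: PipelineConfig
                           ) -> RegionEpochs:
    """Anti-aliased decimation to the analysis rate (skipped in literal mode)."""
    fs = region_epochs.fs_hz
    if config.literal_fs or fs <= config.analysis_fs_hz:
        return region_epochs
    q = int(round(fs / config.analysis_fs_hz))
    if q < 2:
        return region_epochs
    dec = sp_signal.decimate(region_epochs.epochs, q, ftype="fir",
                             zero_phase=True, axis=-1)
    return RegionEpochs(epochs=dec, fs_hz=fs / q,
                        region_labels=list(region_epochs.region_labels))


def connectivity_from_region_epochs(region_epochs: RegionEpochs,
                                    config: PipelineConfig
                                    ) -> dict[str, np.ndarray]:
    """One MVAR fit per epoch, |PDC| averaged over epochs within each band."""
    region_epochs = decimate_region_epochs(region_epochs, config)
    fs = region_epochs.fs_hz
    models = fit_mvar_epochs(region_epochs.epochs, order=config.mvar_order)
    grid = default_freq_grid(fs, config.freq_lo, config.freq_hi, config.freq_step)
    spectra = [pdc_spectrum(m, grid, fs, variant=config.pdc_variant)
               for m in models]
    return band_average(spectra, _bands(config))


def features_for_patient(
    band_conn: dict[str, np.ndarray],
    soz_region: int,
    patient_id: str,
    group: str,
    config: PipelineConfig,
) -> PatientFeatures:
    flows = inflow_outflow(band_conn)
    metrics = {band: node_metrics(threshold_network(band_conn[band],
                                                    config.graph_density))
               for band in band_conn}
    return extract_soz_features(flows, metrics, soz_region, patient_id, group)


def cohort_features(dataset: CohortDataset, config: PipelineConfig
                    ) -> list[PatientFeatures]:
    """In-memory chain over a synthetic cohort (no file round-trip)."""
    feats = []
    for p in dataset.patients:
        region = recording_to_region_epochs(p.recording, p.leadfield, config)
        conn = connectivity_from_region_epochs(region, config)
        feats.append(features_for_patient(conn, p.soz_region, p.patient_id,
                                          p.group, config))
    return feats


def write_cohort(dataset: CohortDataset, out_dir: str | Path) -> Path:
    """Write a cohort as per-patient EDF + truth tensors + lead fields +
    manifest.tsv, the on-disk layout `run_pipeline` consumes."""
    out = Path(out_dir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    (out / "leadfields").mkdir(exist_ok=True)
    rows = []
    for p in dataset.patients:
        edf = out / f"{p.patient_id}.edf"
        rio.write_edf(edf, p.recording)
        truth_path = out / "truth" / f"{p.patient_id}_coeffs.tsv"
        rio.save_truth_coeffs(truth_path, p.truth.coeffs)
        lf_path = out / "leadfields" / f"{p.patient_id}_gain.tsv"
        rio.save_leadfield(lf_path, p.leadfield)
        if p.recording.clean_mask is not None:
            np.savetxt(out / f"{p.patient_id}_clean_mask.tsv",
                       p.recording.clean_mask.astype(int), fmt="%d")
        if p.recording.artifact_refs is not None:
            np.savetxt(out / f"{p.patient_id}_artifact_refs.tsv",
                       p.recording.artifact_refs.T, delimiter="\t")
        rows.append(dict(patient_id=p.patient_id, group=p.group,
                         soz_region=p.soz_region,
                         recording_path=edf.name,
                         truth_path=f"truth/{truth_path.name}",
                         leadfield_path=f"leadfields/{lf_path.name}",
                         seed=p.seed))
    rio.write_manifest(pd.DataFrame(rows), out / "manifest.tsv")
    return out


def _load_patient_inputs(row: pd.Series, base: Path) -> tuple[SensorRecording, LeadField]:
    rec = rio.read_recording(base / row["recording_path"])
    lf = rio.load_leadfield(base / row["leadfield_path"])
    mask_path = base / f"{row['patient_id']}_clean_mask.tsv"
    if mask_path.exists():
        rec.clean_mask = np.loadtxt(mask_path).astype(bool)[: rec.n_samples]
    refs_path = base / f"{row['patient_id']}_artifact_refs.tsv"
    if refs_path.exists():
        rec.artifact_refs = np.loadtxt(refs_path, delimiter="\t").T[:, : rec.n_samples]
    return rec, lf


def run_pipeline(manifest_path: str | Path, config: PipelineConfig,
                 out_dir: str | Path) -> tuple[Path, list[str]]:
    """Run the whole analysis over a manifest; returns (out_dir, failures).

    Per patient: band connectivity matrices and SOZ features (TSV). Cohort
    level: features.tsv, group_stats.tsv (32 rows), boxplots.json, a frozen
    config copy and a log file. A failing patient is logged and skipped;
    its id is returned in the failure list (the CLI exits nonzero if any).
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    t0 = time.time()
    failures: list[str] = []
    feats: list[PatientFeatures] = []
    try:
        manifest = rio.read_manifest(manifest_path)
        config.to_yaml(out / "config_used.yaml")
        log.info("pipeline start: %d patients, config %s",
                 len(manifest), config.config_hash())
        for _, row in manifest.iterrows():
            pid = row["patient_id"]
            stage = "load"
            try:
                rec, lf = _load_patient_inputs(row, base)
                stage = "preprocess/inverse"
                region = recording_to_region_epochs(rec, lf, config)
                stage = "connectivity"
                conn = connectivity_from_region_epochs(region, config)
                stage = "features"
                pdir = out / "patients" / pid
                pdir.mkdir(parents=True, exist_ok=True)
                for band, M in conn.items():
                    np.savetxt(pdir / f"conn_{band}.tsv", M, delimiter="\t")
                f = features_for_patient(conn, int(row["soz_region"]), pid,
                                         row["group"], config)
                pd.DataFrame([f.flat()]).to_csv(pdir / "soz_features.tsv",
                                                sep="\t", index=False)
                feats.append(f)
                log.info("patient %s done", pid)
            except Exception as err:  # noqa: BLE001 - continue-on-error contract
                failures.append(pid)
                log.error("patient %s failed at stage %s: %s", pid, stage, err)
        if feats:
            frame = features_to_frame(feats)
            wide = pd.DataFrame(
                [dict(patient_id=f.patient_id, group=f.group,
                      soz_region=f.soz_region, **f.flat()) for f in feats]
            )
            wide.to_csv(out / "features.tsv", sep="\t", index=False)
            frame.to_csv(out / "features_long.tsv", sep="\t", index=False)
            stats = compare_groups(feats)
            stats.to_csv(out / "group_stats.tsv", sep="\t", index=False)
            box = {}
            for (measure, band), sub in frame.groupby(["measure", "band"]):
                box[f"{measure}_{band}"] = {
                    g: dataclasses.asdict(
                        boxplot_summary(sub[sub.group == g]["value"].to_numpy()))
                    for g in sorted(sub.group.unique())
                }
            (out / "boxplots.json").write_text(json.dumps(box, indent=1,
                                                          sort_keys=True))
        log.info("pipeline finished in %.1f s; %d failures",
                 time.time() - t0, len(failures))
    finally:
        log.removeHandler(handler)
        handler.close()
    return out, failures


def plot_boxplots(features: "list[PatientFeatures] | pd.DataFrame",
                  out_path: str | Path, measure: str = "inflow") -> Path:
    """Boxplot figure of one measure across bands, by outcome group.

    Accepts either the in-memory feature records or the long-format table
    written as features_long.tsv.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = features if isinstance(features, pd.DataFrame) \
        else features_to_frame(features)
    sub = frame[frame.measure == measure]
    fig, axes = plt.subplots(1, len(BAND_ORDER), figsize=(10, 3), sharey=True)
    for ax, band in zip(axes, BAND_ORDER):
        data = [sub[(sub.band == band) & (sub.group == g)]["value"].to_numpy()
                for g in ("seizure_free", "non_seizure_free")]
        ax.boxplot(data, tick_labels=["SF", "NSF"])
        ax.set_title(band)
    axes[0].set_ylabel(measure)
    fig.tight_layout()
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
    return Path(out_path)
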