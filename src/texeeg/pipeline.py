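"""End-to-end study replica: synthesize -> preprocess -> analyze -> compare.

``run_study`` drives the whole characterization from one config object:

* impedance study (three technologies, mean +/- SEM curves, threshold check);
* resting-state (eyes closed / eyes open) and artifact-induction sessions
  for a cohort, both devices, through outlier removal (rest only),
  broadband filtering, PSD, band-power table and per-band paired Wilcoxon
  comparison;
* per-action band comparisons on the artifact task's 10 s segments;
* movement sessions, epoching, trial rejection, Morlet TFR, ERD/ERS maps
  per subject, and the bin-wise masked difference map between devices.

Every stage writes CSV/JSON under the output directory; a manifest records
the seed, config and package version. Identical config + seed yields
byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io_core import AnalysisConfig, Recording, extract_epochs
from .preprocessing import bandpass, bandpass_epochs, reject_trials, \
    remove_amplitude_outliers
from .spectral import band_comparison_table, band_power_table, compute_psd, \
    segment_by_action
from .synthetic import ACTIONS, default_device_profiles, make_cohort, \
    simulate_artifact_session, simulate_movement_session, simulate_resting
from .timefreq import binwise_device_comparison, erds, grand_average_erds, \
    morlet_tfr
from . import impedance as imp

logger = logging.getLogger(__name__)

_TASK_STATE = {"ec_rest": "closed", "eo_rest": "open"}


@dataclass
class PipelineConfig:
    """Study-replica configuration; defaults are the study's conditions."""

    seed: int = 0
    out_dir: str = "texeeg_out"
    n_subjects: int = 10
    n_impedance_subjects: int = 6
    rest_duration_s: float = 180.0
    n_blocks: int = 4
    trials_per_block: int = 20
    run_erds: bool = True
    tfr_decim: int = 8
    make_plots: bool = False
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        ana = d.pop("analysis", None)
        cfg = cls(**d)
        if ana:
            ana = dict(ana)
            for k in ("bands",):
                if k in ana:
                    ana[k] = {b: tuple(v) for b, v in ana[k].items()}
            for k in ("broadband_filter", "movement_filter", "display_filter",
                      "baseline_s", "epoch_window_s"):
                if k in ana:
                    ana[k] = tuple(ana[k])
            cfg.analysis = AnalysisConfig(**ana)
        return cfg


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def _clean_rest(rec: Recording, cfg: AnalysisConfig):
    cleaned, mask = remove_amplitude_outliers(rec, cfg.outlier_hp_hz,
                                              cfg.outlier_z)
    return bandpass(cleaned, *cfg.broadband_filter, cfg.filter_order), mask


def run_study(config: PipelineConfig) -> dict:
    """Run the full study replica and write its report bundle.

    Returns a dict of the in-memory results (tables, maps, paths). Any
    stage failure aborts with the stage name in the exception message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ana = config.analysis
    results: dict = {"out_dir": str(out)}
    rng_seeds = _child_seeds(config.seed, 6)

    stage = "impedance"
    try:
        measurements = imp.simulate_impedance_study(
            n_subjects=config.n_impedance_subjects, seed=int(rng_seeds[0]))
        rows = []
        for tech in imp.TECHNOLOGIES:
            freqs, mean, sem = imp.average_impedance(measurements, tech)
            _, all_below = imp.below_threshold(mean,
                                               ana.wet_impedance_threshold_ohm)
            for f, m, s in zip(freqs, mean, sem):
                rows.append((tech, f, m, s, all_below))
        imp_df = pd.DataFrame(rows, columns=["technology", "freq_hz",
                                             "z_mean_ohm", "z_sem_ohm",
                                             "all_below_5k"])
        imp_df.to_csv(out / "impedance_curves.csv", index=False)
        imp.measurements_to_frame(measurements).to_csv(
            out / "impedance_measurements.csv", index=False)
        results["impedance"] = imp_df
        logger.info("impedance: %d sweeps", len(measurements))

        stage = "synthesis+psd"
        cohort = make_cohort(config.n_subjects, seed=int(rng_seeds[1]))
        devices = default_device_profiles()
        session_seeds = _child_seeds(int(rng_seeds[2]),
                                     config.n_subjects * 2 * 4).reshape(
                                         config.n_subjects, 2, 4)
        spectra = {}
        action_spectra = {}
        rejection_log = []
        for si, profile in enumerate(cohort):
            subj = f"S{si + 1:02d}"
            for di, (dev_name, dev) in enumerate(sorted(devices.items())):
                seeds = session_seeds[si, di]
                for ti, task in enumerate(("ec_rest", "eo_rest")):
                    rec = simulate_resting(profile, dev, _TASK_STATE[task],
                                           config.rest_duration_s,
                                           seed=int(seeds[ti]))
                    rec, mask = _clean_rest(rec, ana)
                    rejection_log.append(
                        (subj, dev_name, task,
                         float(mask.flagged_fraction.mean())))
                    spectra[(subj, dev_name, task)] = compute_psd(rec, ana)
                rec, events = simulate_artifact_session(profile, dev,
                                                        seed=int(seeds[2]))
                filt = bandpass(rec, *ana.broadband_filter, ana.filter_order)
                spectra[(subj, dev_name, "artifact")] = compute_psd(filt, ana)
                for label, seg in segment_by_action(filt, events):
                    action_spectra[(subj, dev_name, "artifact", label)] = \
                        compute_psd(seg, ana)

        table = band_power_table(spectra, ana)
        table.to_csv(out / "band_power.csv", index=False)
        results["band_power"] = table

        stage = "band comparisons"
        comp = pd.concat([band_comparison_table(table, task, cfg=ana)
                          for task in ("ec_rest", "eo_rest", "artifact")],
                         ignore_index=True)
        comp.to_csv(out / "band_comparisons.csv", index=False)
        results["band_comparisons"] = comp

        action_table = band_power_table(action_spectra, ana)
        action_comp = pd.concat(
            [band_comparison_table(action_table, "artifact", action, ana)
             for action in ACTIONS], ignore_index=True)
        action_comp.to_csv(out / "per_action_comparisons.csv", index=False)
        results["per_action_comparisons"] = action_comp

        if config.run_erds:
            stage = "erds"
            erds_seeds = _child_seeds(int(rng_seeds[3]),
                                      config.n_subjects * 2).reshape(
                                          config.n_subjects, 2)
            subject_maps = {"garment": [], "dry": []}
            for si, profile in enumerate(cohort):
                for di, (dev_name, dev) in enumerate(sorted(devices.items())):
                    rec, events = simulate_movement_session(
                        profile, dev, config.n_blocks,
                        config.trials_per_block,
                        seed=int(erds_seeds[si, di]))
                    epochs = extract_epochs(rec, events, "movement",
                                            *ana.epoch_window_s)
                    epochs, kept = reject_trials(epochs, ana.trial_reject_uv)
                    epochs = bandpass_epochs(epochs, *ana.movement_filter,
                                             ana.filter_order)
                    tfr = morlet_tfr(epochs, ana.tfr_fmin, ana.tfr_fmax,
                                     ana.tfr_df, ana.tfr_n_cycles,
                                     decim=config.tfr_decim)
                    maps = erds(tfr, ana.baseline_s)
                    subject_maps[dev_name].append(grand_average_erds(maps))
            p, mask, masked = binwise_device_comparison(
                subject_maps["garment"], subject_maps["dry"],
                ana.alpha_binwise)
            ga = {dev: grand_average_erds(ms)
                  for dev, ms in subject_maps.items()}
            for name, m in (("erds_garment", ga["garment"]),
                            ("erds_dry", ga["dry"]),
                            ("erds_masked_difference", masked)):
                _write_map_csv(out / f"{name}.csv", m.values, m.freqs, m.times)
            _write_map_csv(out / "erds_binwise_p.csv", p, masked.freqs,
                           masked.times)
            results["erds"] = {"garment": ga["garment"], "dry": ga["dry"],
                               "p": p, "mask": mask, "masked_diff": masked}

        stage = "manifest"
        cfg_dict = config.to_dict()
        manifest = {
            "package": "texeeg",
            "version": __version__,
            "seed": config.seed,
            "config": cfg_dict,
            "config_sha256": hashlib.sha256(
                json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest(),
            "outlier_flagged_fraction": {
                f"{s}/{d}/{t}": frac for s, d, t, frac in rejection_log},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        results["manifest"] = manifest
    except Exception as err:
        raise RuntimeError(f"run_study failed at stage {stage!r}: {err}") from err
    return results


def _write_map_csv(path, values, freqs, times):
    df = pd.DataFrame(values, index=np.round(freqs, 4),
                      columns=np.round(times, 4))
    df.index.name = "freq_hz\\time_s"
    df.to_csv(path, float_format="%.6g")


def render_timeseries(rec: Recording, path, display_filter=(0.5, 30.0),
                      window_s: float = 10.0, scale_uv: float | None = None):
    """Plot a 10 s, 4-trace snippet of a recording after display filtering.

    ``scale_uv`` fixes the vertical spacing between traces (so panels of
    the same task state share a scale); defaults to 4x the filtered SD.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if rec.duration_s < window_s:
        raise ValueError(f"recording shorter than {window_s} s")
    filt = bandpass(rec, *display_filter)
    n = int(window_s * rec.fs)
    seg = filt.data[:, :n]
    if scale_uv is None:
        scale_uv = 4 * float(seg.std())
    t = np.arange(n) / rec.fs
    fig, ax = plt.subplots(figsize=(8, 4))
    for i, name in enumerate(rec.channel_names):
        ax.plot(t, seg[i] - i * scale_uv, lw=0.6, label=name)
    ax.set_xlabel("time (s)")
    ax.set_yticks([-i * scale_uv for i in range(rec.n_channels)],
                  rec.channel_names)
    ax.set_title(f"{rec.device or 'EEG'} {rec.task}".strip())
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return Path(path)
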