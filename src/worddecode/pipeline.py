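"""Run configuration and end-to-end orchestration.

A ``RunConfig`` fully determines a run: the same config and seed
regenerate every output file byte-identically.  ``run_all`` chains
simulation, preprocessing, univariate analyses, within/across decoding and
band importance, writing TSV/JSON results plus a machine-readable manifest
(file list with SHA-256 digests) and a log of versions and seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bands import importance_map
from .containers import EpochedDataset
from .design import ExperimentDesign
from .mvpa import ClassifierSpec, WindowSpec, decode_cohort
from .phonetics import load_stimulus_transcriptions, pairwise_distances, stimulus_summary
from .preprocess import baseline_correct, reject_epochs
from .stats import wilcoxon_map
from .synth import GeneratorConfig, simulate_cohort
from .univariate import compute_erp, compute_ersp

__all__ = ["RunConfig", "run_all"]

ALL_STAGES = ("simulate", "preprocess", "erp", "ersp", "decode_within",
              "decode_across", "bands")


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    n_subjects: int = 16
    trials_per_noun_per_language: int = 48
    n_channels: int = 62
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    window: WindowSpec = field(default_factory=lambda: WindowSpec(step_samples=10))
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    n_perm: int = 200
    alpha_subject: float = 0.05
    p0: float = 0.05
    alpha: float = 0.05
    ptp_threshold: float = 150.0
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if "simulate" not in self.stages:
            raise ValueError("the simulate stage cannot be disabled")

    def design(self) -> ExperimentDesign:
        if self.trials_per_noun_per_language == 48:
            return ExperimentDesign(n_channels=self.n_channels)
        return ExperimentDesign.scaled(self.trials_per_noun_per_language,
                                       n_channels=self.n_channels)

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"] = dataclasses.asdict(
            self.generator.replace(seed=self.seed)
        )
        return json.loads(json.dumps(d))  # tuples -> lists, plain types only

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "generator" in d:
            g = dict(d["generator"])
            for key in ("wordform_window_ms", "concept_window_ms",
                        "carrier_freqs_hz"):
                if key in g:
                    g[key] = tuple(g[key])
            d["generator"] = GeneratorConfig(**g)
        if "window" in d:
            w = dict(d["window"])
            if w.get("range_ms") is not None:
                w["range_ms"] = tuple(w["range_ms"])
            d["window"] = WindowSpec(**w)
        if "classifier" in d:
            d["classifier"] = ClassifierSpec(**d["classifier"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


class StageError(RuntimeError):
    pass


def run_all(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the enabled stages and write results under ``out_dir``.

    Returns the manifest dict (also written as ``manifest.json``).  Any
    stage failure aborts with the stage name in the error message.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.generator.replace(seed=config.seed)
    design = config.design()
    outputs: dict[str, list[str]] = {}
    log: list[str] = [
        f"worddecode {__version__} | python {sys.version.split()[0]} | "
        f"numpy {np.__version__}",
        f"seed {config.seed}",
    ]
    stage = "simulate"
    try:
        cohort = simulate_cohort(config.n_subjects, design, cfg)
        schedule = cohort[0].meta
        _write_tsv(schedule, out / "schedule.tsv")
        outputs["simulate"] = ["schedule.tsv"]
        log.append(f"simulate: {config.n_subjects} subjects, "
                   f"{cohort[0].n_trials} animal trials each")

        if "preprocess" in config.stages:
            stage = "preprocess"
            cleaned, rej_rows = [], []
            for s_i, ep in enumerate(cohort):
                ep = baseline_correct(ep)
                ep, logrec = reject_epochs(ep, config.ptp_threshold)
                cleaned.append(ep)
                rej_rows.append(dict(subject=s_i, n_rejected=logrec.n_rejected,
                                     threshold=logrec.threshold))
            cohort = cleaned
            _write_tsv(pd.DataFrame(rej_rows), out / "rejection_log.tsv")
            outputs["preprocess"] = ["rejection_log.tsv"]

        if "erp" in config.stages:
            stage = "erp"
            erps = [compute_erp(ep) for ep in cohort]
            grand = np.mean([e.mean for e in erps], axis=0)
            times = erps[0].times_ms
            frame = pd.DataFrame(
                {"time_ms": np.tile(times, grand.shape[0]),
                 "channel": np.repeat(np.arange(grand.shape[0]), grand.shape[1]),
                 "mean_uv": grand.ravel()}
            )
            _write_tsv(frame, out / "erp.tsv")
            outputs["erp"] = ["erp.tsv"]

        if "ersp" in config.stages:
            stage = "ersp"
            ersps = [compute_ersp(ep) for ep in cohort]
            power = np.stack([e.power_db for e in ersps])
            if len(cohort) >= 6:
                sig, pvals = wilcoxon_map(power, mu=0.0, alpha=config.alpha)
            else:  # too few subjects for group statistics
                pvals = np.full(power.shape[1:], np.nan)
                sig = np.zeros(power.shape[1:], dtype=bool)
            mean_db = power.mean(axis=0)
            e0 = ersps[0]
            frame = pd.DataFrame(
                {"freq_hz": np.repeat(e0.freqs, len(e0.times_ms)),
                 "time_ms": np.tile(e0.times_ms, len(e0.freqs)),
                 "power_db": mean_db.ravel(),
                 "p": pvals.ravel(),
                 "sig_fdr": sig.ravel()}
            )
            _write_tsv(frame, out / "ersp.tsv")
            outputs["ersp"] = ["ersp.tsv"]

        for mode in ("within", "across"):
            key = f"decode_{mode}"
            if key not in config.stages:
                continue
            stage = key
            tc = decode_cohort(
                cohort, mode, config.window, config.classifier,
                n_perm=config.n_perm, seed=config.seed,
                alpha_subject=config.alpha_subject, p0=config.p0,
                alpha=config.alpha, n_speakers=design.n_speakers,
            )
            _write_tsv(tc.to_frame(), out / f"{key}.tsv")
            summary = {
                "mode": mode,
                "max_accuracy": float(tc.accuracy.max()),
                "max_accuracy_window_ms": float(
                    tc.window_centers_ms[int(tc.accuracy.argmax())]
                ),
                "n_sig_windows_fdr": int(tc.group_sig_fdr.sum()),
                "sig_windows_ms": [float(x) for x in
                                   tc.window_centers_ms[tc.group_sig_fdr]],
            }
            _write_json(summary, out / f"{key}_summary.json")
            outputs[key] = [f"{key}.tsv", f"{key}_summary.json"]
            log.append(f"{key}: max acc {summary['max_accuracy']:.3f} at "
                       f"{summary['max_accuracy_window_ms']:.0f} ms")

        if "bands" in config.stages:
            stage = "bands"
            imap = importance_map(
                cohort, "across", config.window, config.classifier,
                alpha=config.alpha, n_speakers=design.n_speakers,
            )
            frame = pd.DataFrame(
                {"band_center_hz": np.repeat(imap.band_centers_hz,
                                             len(imap.window_centers_ms)),
                 "window_center_ms": np.tile(imap.window_centers_ms,
                                             len(imap.band_centers_hz)),
                 "odds_ratio": imap.odds_ratio.ravel(),
                 "p": imap.p.ravel(),
                 "sig_fdr": imap.group_sig.ravel()}
            )
            _write_tsv(frame, out / "band_importance.tsv")
            outputs["bands"] = ["band_importance.tsv"]
    except Exception as exc:  # noqa: BLE001 - annotate with the stage
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    (out / "run.log").write_text("\n".join(log) + "\n")
    manifest = {
        "config": config.to_dict(),
        "outputs": {
            s: [{"file": f, "sha256": _sha256(out / f)} for f in files]
            for s, files in outputs.items()
        },
    }
    _write_json(manifest, out / "manifest.json")
    return manifest


def phonetics_report(fixtures: str | Path | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise distance table and per-group summary for the stimulus set."""
    transcriptions = load_stimulus_transcriptions(fixtures)
    return pairwise_distances(transcriptions), stimulus_summary(transcriptions)
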