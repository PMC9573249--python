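"""End-to-end orchestration over a multi-field image set.

One result-reading chip is imaged as ~100 fields of view, each with one
bright-field frame and one frame per fluorescence channel. Per field and
channel the pipeline runs: droplet detection (bright field) → vignette
correction (fluorescence) → trimmed-mean signal extraction → impurity
suppression → two-means classification → separation quality gate →
counting. Quality-passing fields are pooled into a single Poisson
quantification. All intermediates are written as CSV/JSON so a rerun on
the same inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import imgio
from .blobdetect import DetectorParams, Droplet, detect_droplets, droplets_to_frame
from .classify import ClusterResult, kmeans_1d, quality_gate
from .metrics import quantify
from .signal import SignalParams, extract_signals, suppress_impurities
from .vignette import VignetteModel, correct_image, fit_surface, gaussian_blur_3x3

log = logging.getLogger("dropvision")

__all__ = ["FieldSpec", "RunConfig", "FieldResult", "analyze_field",
           "run_pipeline", "load_run_config"]


@dataclass
class FieldSpec:
    field_id: str
    bright_field: str
    fluorescence: dict[str, str]  # channel name -> path


@dataclass
class RunConfig:
    fields: list[FieldSpec]
    out_dir: str
    detector: DetectorParams = field(default_factory=DetectorParams)
    signal: SignalParams = field(default_factory=SignalParams)
    vignette_template: dict[str, str] = field(default_factory=dict)  # channel -> calibration frame
    vignette_model: dict[str, str] = field(default_factory=dict)  # channel -> model JSON
    blur_passes: int = 50
    sample_stride: int = 8
    min_separation: float | None = None
    pool_signals: bool = False  # cluster all fields jointly instead of per image
    seed: int = 0
    droplet_volume_pl: float = 24.0

    def validate(self) -> None:
        ids = [f.field_id for f in self.fields]
        if len(set(ids)) != len(ids):
            raise ValueError("field ids must be unique")
        if not self.fields:
            raise ValueError("run config lists no fields")


@dataclass
class FieldResult:
    """Per-field, per-channel outcome of the analysis chain."""
    field_id: str
    channel: str
    droplets: list[Droplet]
    cluster: ClusterResult | None
    n_detected: int
    n_edge: int
    n_rejected: int
    n_pos: int
    n_neg: int
    quality_ok: bool

    @property
    def positive_fraction(self) -> float | None:
        tot = self.n_pos + self.n_neg
        return self.n_pos / tot if tot else None


def analyze_field(bright_field: np.ndarray, fluor: np.ndarray,
                  detector: DetectorParams | None = None,
                  vignette_model: VignetteModel | None = None,
                  signal_params: SignalParams | None = None,
                  min_separation: float | None = None,
                  seed: int = 0,
                  field_id: str = "field", channel: str = "ch0",
                  droplets: list[Droplet] | None = None) -> FieldResult:
    """Run the per-field chain on in-memory images.

    ``droplets`` may carry a precomputed detection (e.g. shared across
    channels of the same field); otherwise detection runs here.
    """
    detector = detector or DetectorParams()
    signal_params = signal_params or SignalParams()
    if droplets is None:
        droplets = detect_droplets(bright_field, detector)
    corrected = (correct_image(fluor, vignette_model)
                 if vignette_model is not None
                 else np.asarray(fluor, dtype=np.float64))
    usable = [d for d in droplets if not d.edge_flag]
    extract_signals(corrected, usable, signal_params)
    suppress_impurities(usable, corrected, signal_params)
    classifiable = [d for d in usable if d.label != "rejected"]

    cluster = None
    quality = False
    if len({d.signal for d in classifiable}) >= 2:
        cluster = kmeans_1d([d.signal for d in classifiable], seed=seed)
        quality = quality_gate(cluster, min_separation)
        for d, lab in zip(classifiable, cluster.labels):
            d.label = str(lab)
    n_pos = sum(1 for d in classifiable if d.label == "positive")
    n_neg = sum(1 for d in classifiable if d.label == "negative")
    return FieldResult(
        field_id=field_id, channel=channel, droplets=droplets,
        cluster=cluster,
        n_detected=len(droplets),
        n_edge=sum(1 for d in droplets if d.edge_flag),
        n_rejected=sum(1 for d in usable if d.label == "rejected"),
        n_pos=n_pos, n_neg=n_neg, quality_ok=quality)


def _fit_channel_models(config: RunConfig) -> dict[str, VignetteModel]:
    models: dict[str, VignetteModel] = {}
    for channel, path in config.vignette_model.items():
        models[channel] = VignetteModel.from_json(path)
    for channel, path in config.vignette_template.items():
        if channel in models:
            continue
        frame = imgio.read_gray(path)
        template = gaussian_blur_3x3(frame, passes=config.blur_passes)
        models[channel] = fit_surface(template, sample_stride=config.sample_stride)
    return models


def run_pipeline(config: RunConfig) -> dict:
    """Process every field in the manifest; returns the run summary.

    Unreadable or mismatched fields are logged, recorded in the summary
    and skipped; the run fails only if no field survives. Writes
    ``droplets_<field>_<channel>.csv`` per field, ``summary.csv``,
    ``summary.json`` and ``run.log`` under the output directory.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        models = _fit_channel_models(config)
        rows = []
        skipped = []
        pooled: dict[str, list[Droplet]] = {}
        for fs in sorted(config.fields, key=lambda f: f.field_id):
            try:
                bf = imgio.read_gray(fs.bright_field)
                droplets = detect_droplets(bf, config.detector)
            except Exception as exc:  # noqa: BLE001 - per-field fault barrier
                log.warning("field %s skipped: %s", fs.field_id, exc)
                skipped.append({"field_id": fs.field_id, "reason": str(exc)})
                continue
            for channel in sorted(fs.fluorescence):
                try:
                    fl = imgio.read_gray(fs.fluorescence[channel])
                    res = analyze_field(
                        bf, fl, detector=config.detector,
                        vignette_model=models.get(channel),
                        signal_params=config.signal,
                        min_separation=config.min_separation,
                        seed=config.seed, field_id=fs.field_id,
                        channel=channel,
                        droplets=[dataclasses.replace(d) for d in droplets])
                except Exception as exc:  # noqa: BLE001
                    log.warning("field %s channel %s skipped: %s",
                                fs.field_id, channel, exc)
                    skipped.append({"field_id": fs.field_id,
                                    "channel": channel, "reason": str(exc)})
                    continue
                frame = droplets_to_frame(res.droplets)
                frame.to_csv(out / f"droplets_{fs.field_id}_{channel}.csv",
                             index=False)
                pooled.setdefault(channel, []).extend(
                    d for d in res.droplets
                    if not d.edge_flag and d.label != "rejected")
                log.info("field %s channel %s: %d detected, %d pos, %d neg, "
                         "%d rejected, gate=%s", fs.field_id, channel,
                         res.n_detected, res.n_pos, res.n_neg,
                         res.n_rejected, res.quality_ok)
                rows.append({
                    "field_id": fs.field_id, "channel": channel,
                    "n_detected": res.n_detected, "n_edge": res.n_edge,
                    "n_rejected": res.n_rejected, "n_pos": res.n_pos,
                    "n_neg": res.n_neg,
                    "center_pos": res.cluster.center_pos if res.cluster else None,
                    "center_neg": res.cluster.center_neg if res.cluster else None,
                    "separation": res.cluster.separation if res.cluster else None,
                    "quality_ok": res.quality_ok,
                })
        if not rows:
            raise RuntimeError("no field produced a result; see run.log")
        summary_frame = pd.DataFrame(rows)
        summary_frame.to_csv(out / "summary.csv", index=False)

        channels = {}
        for channel in sorted({r["channel"] for r in rows}):
            ch_rows = [r for r in rows if r["channel"] == channel
                       and r["quality_ok"]]
            if config.pool_signals:
                # Joint clustering of all fields' signals for this channel
                # instead of summing per-image counts.
                signals = [d.signal for d in pooled.get(channel, [])
                           if d.signal is not None]
                if len(set(signals)) >= 2:
                    cluster = kmeans_1d(signals, seed=config.seed)
                    quality_gate(cluster, config.min_separation)
                    n_pos, n_neg = cluster.n_pos, cluster.n_neg
                else:
                    n_pos = n_neg = 0
            else:
                n_pos = sum(r["n_pos"] for r in ch_rows)
                n_neg = sum(r["n_neg"] for r in ch_rows)
            entry = {"n_fields_passing": len(ch_rows),
                     "n_pos": n_pos, "n_neg": n_neg}
            if n_pos + n_neg > 0 and n_neg > 0:
                q = quantify(n_pos, n_neg, config.droplet_volume_pl)
                entry.update(positive_fraction=q.positive_fraction,
                             lam=q.lam, concentration_copies_per_pl=q.concentration,
                             concentration_copies_per_ul=q.copies_per_ul)
            channels[channel] = entry
        summary = {"channels": channels, "skipped": skipped,
                   "n_fields": len({r["field_id"] for r in rows})}
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        return summary
    finally:
        log.removeHandler(handler)
        handler.close()


def load_run_config(path) -> RunConfig:
    """Read a run configuration from YAML or JSON."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    fields = [FieldSpec(field_id=str(f["field_id"]),
                        bright_field=f["bright_field"],
                        fluorescence=dict(f["fluorescence"]))
              for f in data["fields"]]
    detector = DetectorParams(**data.get("detector", {}))
    sig = SignalParams(**data.get("signal", {}))
    return RunConfig(
        fields=fields, out_dir=data["out_dir"], detector=detector, signal=sig,
        vignette_template=dict(data.get("vignette_template", {})),
        vignette_model=dict(data.get("vignette_model", {})),
        blur_passes=int(data.get("blur_passes", 50)),
        sample_stride=int(data.get("sample_stride", 8)),
        min_separation=data.get("min_separation"),
        pool_signals=bool(data.get("pool_signals", False)),
        seed=int(data.get("seed", 0)),
        droplet_volume_pl=float(data.get("droplet_volume_pl", 24.0)))
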