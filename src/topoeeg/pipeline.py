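"""Run configuration and stage chaining for reproducible end-to-end runs.

``RunConfig`` aggregates every stage's settings into one JSON-serializable
document with strict key validation (unknown keys are rejected by name).
All randomness flows from the single global seed, fanned out to named
substreams per stage, so a run is fully reproducible from its persisted
config.json.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace

import numpy as np

from .preprocess import DEFAULT_BANDS, band_windows
from .synthetic import (SyntheticCohortConfig, SyntheticSubject, generate_cohort,
                        substream_rng)
from .tda import TDAConfig, diagram_to_pi, pooled_pi_ranges, window_to_diagram
from .train_eval import TrainingConfig

__all__ = [
    "RunConfig",
    "desk_scale_config",
    "extract_pi_sequences",
]


def _from_dict(cls, data: dict, path: str = ""):
    """Instantiate a (possibly nested) dataclass, rejecting unknown keys."""
    known = {f.name: f for f in fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in known:
            raise ValueError(f"unknown config key: {path}{key}")
        target = _NESTED.get((cls.__name__, key))
        if target is not None and isinstance(value, dict):
            kwargs[key] = _from_dict(target, value, path=f"{path}{key}.")
        else:
            kwargs[key] = value
    return cls(**kwargs)


@dataclass
class RunConfig:
    """All module configs plus the global seed.

    ``band`` selects which frequency band's PI sequences the training run
    uses (the full pipeline is per-band, one model per band).
    """

    cohort: SyntheticCohortConfig = field(default_factory=SyntheticCohortConfig)
    tda: TDAConfig = field(default_factory=TDAConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    band: str = "Alpha"
    window_s: float = 4.0
    collapse: str = "mean"
    prefilter: bool = False
    neighborhood: int = 8
    gat_hidden: int = 8
    clinical_epochs: int = 500
    clinical_lr: float = 1e-3
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        # tuples -> lists for lossless JSON round-tripping
        return _jsonify(d)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        cfg = _from_dict(cls, _tuplify(data))
        for name in ("cohort", "tda", "training"):
            sub = getattr(cfg, name)
            if isinstance(sub, dict):
                raise TypeError(f"{name} must be a mapping of config keys")
        return cfg

    def resolved(self) -> "RunConfig":
        """Copy with per-stage seeds derived from the global seed."""
        def sub_seed(label: str) -> int:
            return int(substream_rng(self.seed, label).integers(2**31))
        return replace(
            self,
            cohort=replace(self.cohort, seed=sub_seed("cohort")),
            tda=replace(self.tda, seed=sub_seed("tda")),
            training=replace(self.training, seed=sub_seed("training")),
        )


_NESTED = {
    ("RunConfig", "cohort"): SyntheticCohortConfig,
    ("RunConfig", "tda"): TDAConfig,
    ("RunConfig", "training"): TrainingConfig,
}


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


_TUPLE_KEYS = {"hom_dims", "birth_range", "pers_range"}


def _tuplify(data):
    out = {}
    for k, v in data.items():
        if isinstance(v, dict):
            out[k] = _tuplify(v)
        elif isinstance(v, list) and k in _TUPLE_KEYS:
            out[k] = tuple(v)
        else:
            out[k] = v
    return out


def desk_scale_config(seed: int = 0, n_subjects_per_class: int = 10,
                      duration_s: float = 40.0, band: str = "Alpha",
                      resolution: int = 20) -> RunConfig:
    """A configuration sized for single-CPU runs.

    Shrinks the cohort duration, image resolution (20 instead of 100), the
    embedded clouds (40 points, H1 only) and the epoch budgets; everything
    else keeps the full-scale defaults.
    """
    return RunConfig(
        cohort=SyntheticCohortConfig(
            n_subjects_per_class=n_subjects_per_class,
            duration_s=duration_s, seed=seed),
        tda=TDAConfig(max_points=40, max_hom_dim=1, hom_dims=(1,),
                      resolution=resolution, seed=seed),
        training=TrainingConfig(resolution=resolution, epochs_pretrain=20,
                                epochs_joint=50, seed=seed),
        band=band,
        seed=seed,
    )


def extract_pi_sequences(subjects: list[SyntheticSubject], band: str,
                         tda_cfg: TDAConfig, window_s: float = 4.0,
                         collapse: str = "mean", prefilter: bool = False):
    """Band-filter, window, embed and vectorize a cohort into PI sequences.

    Persistence-image axis ranges are pooled over every diagram of the
    cohort (then frozen into the returned TDAConfig) so that images are
    comparable across windows and subjects — a requirement for using them
    as prediction targets.  Returns ({(subject_id, band): (T, R, R)},
    fitted TDAConfig).
    """
    band_def = next(b for b in DEFAULT_BANDS if b.name == band)
    diagrams_per_subject = {}
    all_diagrams = []
    for s in subjects:
        wins = band_windows(s.recording, (band_def,), window_s,
                            collapse=collapse, prefilter=prefilter)[band]
        diags = [window_to_diagram(w.data, tda_cfg) for w in wins]
        diagrams_per_subject[s.recording.subject_id] = diags
        all_diagrams.extend(diags)
    if tda_cfg.birth_range is None or tda_cfg.pers_range is None:
        birth_range, pers_range = pooled_pi_ranges(all_diagrams, tda_cfg.hom_dims)
        tda_cfg = replace(tda_cfg, birth_range=birth_range, pers_range=pers_range)
    sequences = {}
    for sid, diags in diagrams_per_subject.items():
        stack = np.stack([
            diagram_to_pi(d, resolution=tda_cfg.resolution, sigma=tda_cfg.sigma,
                          hom_dims=tda_cfg.hom_dims,
                          birth_range=tda_cfg.birth_range,
                          pers_range=tda_cfg.pers_range).pixels
            for d in diags
        ])
        sequences[(sid, band)] = stack
    return sequences, tda_cfg


def simulate(cfg: RunConfig) -> list[SyntheticSubject]:
    """Generate the cohort described by cfg (after seed resolution)."""
    return generate_cohort(cfg.cohort)
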