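"""Flat key/value analysis configuration.

Config files are plain text, one ``key = value`` per line, ``#`` comments
allowed; every key mirrors a tunable analysis parameter. Unknown keys are
rejected so typos fail loudly.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, fields


@dataclass
class AnalysisConfig:
    """All tunable parameters of the feature-extraction pipeline."""

    filter_low_hz: float = 1.0
    filter_high_hz: float = 45.0
    edge_trim_s: float = 2.0
    epoch_length_s: float = 2.0
    epoch_overlap_spectral: float = 0.25
    epoch_overlap_bicoherence: float = 0.75
    epoch_overlap_coherence: float = 0.25
    epoch_overlap_entropy: float = 0.25
    cwt_step_hz: float = 1.0
    cwt_bandwidth_hz: float = 2.0
    fiwbic_aggregate: str = "mean"
    coh_window_overlap: float = 0.5
    ent_apen_m: int = 2
    ent_apen_r: float = 0.2
    ent_saen_m: int = 2
    ent_saen_r: float = 0.2
    ent_peen_order: int = 3
    ent_peen_delay: int = 2
    ent_peen_log: str = "e"
    ent_waen_levels: int = 5
    ent_waen_mother: str = "db4"
    ent_waen_normalized: bool = True
    stats_fdr_scope: str = "family"
    stats_ttest: str = "student"
    stats_alpha: float = 0.05

    @property
    def peen_log_base(self) -> float:
        return math.e if self.ent_peen_log == "e" else float(self.ent_peen_log)

    def hash(self) -> str:
        text = ";".join(f"{f.name}={getattr(self, f.name)}" for f in fields(self))
        return hashlib.sha256(text.encode()).hexdigest()[:16]


#: file key -> (attribute, parser)
_KEYMAP = {
    "filter.low_hz": ("filter_low_hz", float),
    "filter.high_hz": ("filter_high_hz", float),
    "edge.trim_s": ("edge_trim_s", float),
    "epoch.length_s": ("epoch_length_s", float),
    "epoch.overlap.spectral": ("epoch_overlap_spectral", float),
    "epoch.overlap.bicoherence": ("epoch_overlap_bicoherence", float),
    "epoch.overlap.coherence": ("epoch_overlap_coherence", float),
    "epoch.overlap.entropy": ("epoch_overlap_entropy", float),
    "cwt.step_hz": ("cwt_step_hz", float),
    "cwt.bandwidth_hz": ("cwt_bandwidth_hz", float),
    "fiwbic.aggregate": ("fiwbic_aggregate", str),
    "coh.window_overlap": ("coh_window_overlap", float),
    "ent.apen.m": ("ent_apen_m", int),
    "ent.apen.r": ("ent_apen_r", float),
    "ent.saen.m": ("ent_saen_m", int),
    "ent.saen.r": ("ent_saen_r", float),
    "ent.peen.order": ("ent_peen_order", int),
    "ent.peen.delay": ("ent_peen_delay", int),
    "ent.peen.log": ("ent_peen_log", str),
    "ent.waen.levels": ("ent_waen_levels", int),
    "ent.waen.mother": ("ent_waen_mother", str),
    "ent.waen.normalized": ("ent_waen_normalized",
                            lambda s: s.lower() in ("1", "true", "yes")),
    "stats.fdr.scope": ("stats_fdr_scope", str),
    "stats.ttest": ("stats_ttest", str),
    "stats.alpha": ("stats_alpha", float),
}


def load_config(path=None) -> AnalysisConfig:
    """Parse a flat key/value config file; defaults when `path` is None."""
    cfg = AnalysisConfig()
    if path is None:
        return cfg
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, raw = line.partition("=")
            key = key.strip()
            if key not in _KEYMAP:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            attr, parse = _KEYMAP[key]
            setattr(cfg, attr, parse(raw.strip()))
    return cfg


def save_config(cfg: AnalysisConfig, path) -> None:
    inv = {attr: key for key, (attr, _) in _KEYMAP.items()}
    with open(path, "w") as fh:
        for f in fields(cfg):
            fh.write(f"{inv[f.name]} = {getattr(cfg, f.name)}\n")
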