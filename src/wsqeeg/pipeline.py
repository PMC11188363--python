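"""End-to-end orchestration: preprocessing -> features -> statistics.

``extract_features`` turns per-subject recordings into the subject x
feature table (families ``rp``, ``fiwbic``, ``coh``, ``ent``; 796 features
for a 19-channel montage with the default band scheme), and
``run_full_analysis`` produces the comparison, channel t-map and etiology
TSV reports. Everything is deterministic given inputs and config; the
table carries a provenance hash so reruns can be compared.
"""

from __future__ import annotations

import logging
import os
from collections import defaultdict

import numpy as np
import pandas as pd

from . import __version__
from .complexity import EntropyParams, complexity_features
from .config import AnalysisConfig
from .connectivity import connectivity_features
from .bicoherence import cfc_features
from .group_stats import (channel_tmap, compare_groups, comparison_frame,
                          parse_feature_name, regress_etiology,
                          regression_frame)
from .preprocess import preprocess
from .signal_io import (FeatureTable, Recording, SubjectMeta, check_montage,
                        read_recording, write_feature_table)
from .spectral import BandScheme, spectral_features

logger = logging.getLogger("wsqeeg")

ALL_FAMILIES = ("rp", "fiwbic", "coh", "ent")


def load_cohort_dir(in_dir, fs: float | None = None) -> dict[str, list[Recording]]:
    """Read every recording in a directory, grouped by subject.

    Files are named ``<subject>_seg<k>.(tsv|edf)``; a file without the
    segment suffix is a single-segment subject. Unreadable files skip
    their subject with a logged reason instead of aborting the run.
    """
    by_subject: dict[str, list] = defaultdict(list)
    for name in sorted(os.listdir(in_dir)):
        stem, ext = os.path.splitext(name)
        if ext.lower() not in (".tsv", ".edf", ".txt", ".csv"):
            continue
        if stem == "metadata":
            continue
        sid, _, seg = stem.rpartition("_seg")
        if not sid:
            sid = stem
        by_subject[sid].append(os.path.join(in_dir, name))

    out: dict[str, list[Recording]] = {}
    for sid, paths in by_subject.items():
        try:
            out[sid] = [read_recording(p, fs=fs, subject_id=sid)
                        for p in sorted(paths)]
        except Exception as err:  # noqa: BLE001 - skip-and-log contract
            logger.warning("skipping subject %s: %s", sid, err)
    return out


def extract_subject_features(segments: list[Recording],
                             config: AnalysisConfig | None = None,
                             families=ALL_FAMILIES,
                             scheme: BandScheme | None = None,
                             ent_measures=("apen", "saen", "peen", "waen"),
                             ) -> dict[str, float]:
    """All requested feature families of one subject.

    Segments are conditioned (CAR, 1-45 Hz FIR, edge trim) once and every
    estimator runs on the conditioned signals with its own epoching.
    """
    config = config or AnalysisConfig()
    scheme = scheme or BandScheme()
    prepped = [preprocess(r, config.filter_low_hz, config.filter_high_hz,
                          config.edge_trim_s) for r in segments]
    feats: dict[str, float] = {}
    if "rp" in families:
        feats.update(spectral_features(
            prepped, scheme, config.epoch_length_s, config.epoch_overlap_spectral))
    if "fiwbic" in families:
        feats.update(cfc_features(
            prepped, scheme, bandwidth_hz=config.cwt_bandwidth_hz,
            epoch_s=config.epoch_length_s,
            overlap_frac=config.epoch_overlap_bicoherence,
            aggregate=config.fiwbic_aggregate))
    if "coh" in families:
        feats.update(connectivity_features(
            prepped, scheme, window_s=config.epoch_length_s,
            window_overlap=config.coh_window_overlap))
    if "ent" in families:
        params = EntropyParams(
            apen_m=config.ent_apen_m, apen_r=config.ent_apen_r,
            saen_m=config.ent_saen_m, saen_r=config.ent_saen_r,
            peen_order=config.ent_peen_order, peen_delay=config.ent_peen_delay,
            peen_log_base=config.peen_log_base,
            waen_levels=config.ent_waen_levels,
            waen_mother=config.ent_waen_mother,
            waen_normalized=config.ent_waen_normalized)
        feats.update(complexity_features(
            prepped, params, epoch_s=config.epoch_length_s,
            overlap_frac=config.epoch_overlap_entropy, measures=ent_measures))
    return feats


def extract_features(subjects: dict[str, list[Recording]],
                     config: AnalysisConfig | None = None,
                     families=ALL_FAMILIES,
                     scheme: BandScheme | None = None,
                     ent_measures=("apen", "saen", "peen", "waen"),
                     allow_partial_montage: bool = False) -> FeatureTable:
    """Subject x feature table over a whole cohort.

    Each subject's recordings must pass the 19-electrode montage check
    unless `allow_partial_montage`; a subject whose extraction fails is
    skipped with a logged reason, not fatal to the run.
    """
    config = config or AnalysisConfig()
    rows: list[tuple[str, dict[str, float]]] = []
    for sid in sorted(subjects):
        segments = subjects[sid]
        issues = check_montage(segments[0])
        if issues and not allow_partial_montage:
            logger.warning("skipping subject %s: montage mismatch %s", sid, issues)
            continue
        try:
            feats = extract_subject_features(segments, config, families,
                                             scheme, ent_measures)
        except Exception as err:  # noqa: BLE001 - skip-and-log contract
            logger.warning("skipping subject %s: %s", sid, err)
            continue
        logger.info("subject %s: %d segments, %d features",
                    sid, len(segments), len(feats))
        rows.append((sid, feats))
    if not rows:
        raise ValueError("no subject produced features")
    names = list(rows[0][1])
    values = np.array([[r[1].get(n, np.nan) for n in names] for r in rows])
    provenance = {"config_hash": config.hash(), "package_version": __version__}
    return FeatureTable([r[0] for r in rows], names, values, provenance)


def run_full_analysis(table: FeatureTable, meta: list[SubjectMeta],
                      config: AnalysisConfig | None = None,
                      out_dir=None) -> dict:
    """Group comparison + etiology regression; optionally write all reports.

    Returns a dict with the comparison and regression frames and a
    per-family summary of significant-feature counts.
    """
    config = config or AnalysisConfig()
    known = {m.subject_id for m in meta}
    missing = [s for s in table.subjects if s not in known]
    if missing:
        raise ValueError(f"metadata missing for subjects: {missing}")

    results = compare_groups(table, meta, alpha=config.stats_alpha,
                             fdr_scope=config.stats_fdr_scope,
                             equal_var=config.stats_ttest == "student")
    comp = comparison_frame(results)
    try:
        regr = regression_frame(regress_etiology(table, meta,
                                                 alpha=config.stats_alpha))
    except ValueError as err:
        logger.warning("etiology regression skipped: %s", err)
        regr = pd.DataFrame(columns=["feature", "beta_structural",
                                     "beta_genetic", "p_structural",
                                     "p_genetic", "q_structural",
                                     "q_genetic", "valid"])

    summary_rows = []
    fams = comp["feature"].map(lambda n: parse_feature_name(n)[0])
    for fam in sorted(fams.unique()):
        block = comp[fams == fam]
        summary_rows.append({
            "family": fam,
            "n_features": len(block),
            "n_significant": int(block["significant"].sum()),
            "significant_global": ",".join(
                r.feature for r in block.itertuples()
                if r.significant and r.feature.endswith(".global")),
        })
    summary = pd.DataFrame(summary_rows)

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        comp.to_csv(os.path.join(out_dir, "comparison.tsv"), sep="\t",
                    index=False, float_format="%.12g", na_rep="NA")
        regr.to_csv(os.path.join(out_dir, "etiology.tsv"), sep="\t",
                    index=False, float_format="%.12g", na_rep="NA")
        summary.to_csv(os.path.join(out_dir, "summary.tsv"), sep="\t",
                       index=False)
        seen = set()
        for name in table.feature_names:
            fam, mid, scope = parse_feature_name(name)
            if scope == "channel" and fam != "coh" and (fam, mid) not in seen:
                seen.add((fam, mid))
                channel_tmap(results, fam, mid).to_csv(
                    os.path.join(out_dir, f"tmap.{fam}.{mid}.tsv"), sep="\t",
                    index=False, float_format="%.12g")
    return {"comparison": comp, "etiology": regr, "summary": summary}


def save_features(table: FeatureTable, path) -> None:
    write_feature_table(table, path)
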