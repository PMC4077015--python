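"""End-to-end pipeline: simulate or load recordings, analyze, write a report.

The run configuration is a flat YAML file with either a ``simulate`` block
(cohort shape plus any generator overrides) or a ``recordings`` list
(native .bin+.json or EDF signal paths with an events TSV or layout JSON
each), an optional ``analysis`` block of :class:`AnalysisConfig` overrides,
a ``seed`` and an ``out_dir``.  Outputs are tidy TSV tables plus a JSON
manifest; with a fixed seed two runs produce byte-identical files.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assr_state import combined_isi_power
from .cohort import analyze_cohort, per_animal_means
from .lfp_io import (
    AnalysisConfig,
    Recording,
    SessionLayout,
    StimulusEvent,
    analysis_config_from_dict,
    read_events,
    read_layout,
    read_recording,
)
from .stats_report import (
    anova_summary_rows,
    comparison_table,
    group_compare_tidy,
    make_report,
    mixed_rm_anova,
    write_tsv,
)
from .synthetic_data import SimulationConfig, make_genotype_cohort

logger = logging.getLogger(__name__)

#: bands whose state transition is assessed with the mixed-design ANOVA
STATE_ANOVA_BANDS = ("21-30", "35-44", "71-80")


def layout_from_events(
    events: list[StimulusEvent], duration_s: float, t0: float = 0.0
) -> SessionLayout:
    """Reconstruct the session partition from an event table alone.

    Epoch boundaries: pre ends at the first train onset; the 40-Hz session
    runs until the first 20-Hz train (or one median inter-train interval
    past its last train); post covers the remainder.
    """
    ev40 = sorted(
        (e for e in events if e.session_label == "assr40"), key=lambda e: e.onset_s
    )
    ev20 = sorted(
        (e for e in events if e.session_label == "assr20"), key=lambda e: e.onset_s
    )
    if not ev40 or not ev20:
        raise ValueError("need events from both ASSR sessions to infer a layout")
    onsets = [e.onset_s for e in ev40 + ev20]
    isi = float(np.median(np.diff(sorted(onsets)))) if len(onsets) > 1 else 20.0
    t_40 = ev40[0].onset_s
    t_20 = ev20[0].onset_s
    t_post = min(ev20[-1].onset_s + isi, duration_s)
    epochs = [
        ("pre", t0, t_40),
        ("assr40", t_40, t_20),
        ("assr20", t_20, t_post),
    ]
    if t_post < duration_s:
        epochs.append(("post", t_post, duration_s))
    return SessionLayout(epochs=epochs, events=ev40 + ev20)


def _load_inputs(config: dict, seed: int | None):
    if "simulate" in config:
        sim = dict(config["simulate"])
        n_control = int(sim.pop("n_control", 1))
        n_mutant = int(sim.pop("n_mutant", 0))
        n_channels = int(sim.pop("n_channels", 1))
        sim_seed = int(sim.pop("seed", 0)) if seed is None else int(seed)
        sim_cfg = SimulationConfig(**sim)
        logger.info(
            "simulating cohort: %d control + %d mutant x %d channels, seed %d",
            n_control, n_mutant, n_channels, sim_seed,
        )
        return make_genotype_cohort(n_control, n_mutant, n_channels, sim_cfg, sim_seed)
    if "recordings" in config:
        cohort = []
        for entry in config["recordings"]:
            rec = read_recording(entry["signal"], entry.get("header"))
            if "animal_id" in entry:
                rec.animal_id = str(entry["animal_id"])
            if "genotype" in entry:
                rec.genotype = str(entry["genotype"])
            if "layout" in entry:
                layout = read_layout(entry["layout"])
            elif "events" in entry:
                layout = layout_from_events(
                    read_events(entry["events"]), rec.duration_s, rec.t0
                )
            else:
                raise ValueError(
                    f"recording {entry.get('signal')} needs an 'events' or 'layout' entry"
                )
            cohort.append((rec, layout))
        return cohort
    raise ValueError("config must contain a 'simulate' or 'recordings' section")


def _spectra_frames(analyses, session: str):
    """Wide spectra tables (freq + one column per channel / per animal)."""
    rel, plf = {}, {}
    freqs = None
    for an in analyses:
        for res in an.session_results.get(session, []):
            col = f"{an.animal_id}/{res.channel_id}"
            freqs = res.relative_spectrum.freqs_hz
            rel[col] = res.relative_spectrum.power
            plf[col] = res.plf.plf
    if freqs is None:
        return None, None, None, None
    rel_df = pd.DataFrame({"freq_hz": freqs, **rel})
    plf_df = pd.DataFrame({"freq_hz": freqs, **plf})

    def per_animal(df):
        out = {"freq_hz": df["freq_hz"]}
        animals = sorted({c.split("/")[0] for c in df.columns if c != "freq_hz"})
        for a in animals:
            cols = [c for c in df.columns if c.startswith(f"{a}/")]
            out[a] = df[cols].mean(axis=1)
        return pd.DataFrame(out)

    return rel_df, plf_df, per_animal(rel_df), per_animal(plf_df)


#: (session, band) contrasts reported in the group-comparison table
GROUP_CONTRASTS = (
    ("assr40", "35-44"),
    ("assr40", "75-84"),
    ("assr20", "15-24"),
    ("assr20", "35-44"),
)
PRE_BANDS = ("30-50", "50-100", "100-120")


def _append_comparison(rows, values, value_col, measure, band, design) -> None:
    """Add a genotype contrast; skipped when a group is too small to test."""
    try:
        rows.append(group_compare_tidy(values, value_col, measure, band, design))
    except ValueError as err:
        logger.info("skipping %s %s (%s): %s", measure, band, design, err)


def _group_stats(band_table, state_table) -> pd.DataFrame:
    rows = []
    have_both = set(band_table["genotype"].unique()) >= {"control", "mutant"}
    if not have_both:
        return comparison_table(rows)
    for session, band in GROUP_CONTRASTS:
        sub = band_table[
            (band_table["session"] == session) & (band_table["band"] == band)
        ]
        if sub.empty:
            continue
        for measure in ("relative_power", "plf", "n1_amp_z"):
            per_an = per_animal_means(sub, measure)
            _append_comparison(rows, per_an, measure, f"{session}_{measure}", band, "per_animal")
            _append_comparison(rows, sub, measure, f"{session}_{measure}", band, "per_channel")
    for band in PRE_BANDS:
        pre = state_table[(state_table["epoch"] == "Pre") & (state_table["band"] == band)]
        if pre.empty:
            continue
        per_an = per_animal_means(pre, "mean_power")
        _append_comparison(rows, per_an, "mean_power", "pre_power", band, "per_animal")
        _append_comparison(rows, pre, "mean_power", "pre_power", band, "per_channel")
        isi = combined_isi_power(state_table, band)
        if not isi.empty:
            per_an = per_animal_means(isi, "mean_power")
            _append_comparison(rows, per_an, "mean_power", "isi_combined_power", band, "per_animal")
            _append_comparison(rows, isi, "mean_power", "isi_combined_power", band, "per_channel")
    return comparison_table(rows)


def _state_anovas(state_table) -> tuple[pd.DataFrame, pd.DataFrame]:
    summaries, posthocs = [], []
    n_geno = state_table.groupby("genotype")["animal_id"].nunique()
    enough = (n_geno >= 2).sum() == 2
    for band in STATE_ANOVA_BANDS:
        sub = state_table[state_table["band"] == band]
        if sub.empty or not enough:
            continue
        for design in ("per_animal", "per_channel"):
            res = mixed_rm_anova(sub, design=design)
            summaries.extend(anova_summary_rows(band, design, res))
            ph = res.posthoc.copy()
            ph.insert(0, "band", band)
            ph.insert(1, "design", design)
            posthocs.append(ph)
    summary_df = pd.DataFrame(summaries)
    posthoc_df = (
        pd.concat(posthocs, ignore_index=True) if posthocs else pd.DataFrame()
    )
    return summary_df, posthoc_df


def run_pipeline(
    config: dict | str | Path,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> Path:
    """Simulate-or-load, analyze and report; returns the report directory."""
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text()) or {}
    out_dir = Path(out_dir or config.get("out_dir", "results/run"))
    cfg = analysis_config_from_dict(config.get("analysis", {}))
    seed_used = seed if seed is not None else config.get("seed")

    cohort = _load_inputs(config, seed_used)
    logger.info("analyzing %d recordings", len(cohort))
    state_bands = dict(cfg.bands)
    state_bands.setdefault("30-100", (30.0, 100.0))
    analyses, band_table, state_table = analyze_cohort(cohort, cfg, state_bands)

    results: dict = {
        "band_values": band_table,
        "band_values_per_animal": (
            band_table.groupby(["animal_id", "genotype", "session", "band"], as_index=False)[
                ["n1_amp_z", "relative_power", "evoked_power", "plf"]
            ].mean()
        ),
        "state_table": state_table,
    }
    for session in ("assr40", "assr20"):
        rel, plf, rel_an, plf_an = _spectra_frames(analyses, session)
        if rel is None:
            continue
        results[f"relative_spectra_{session}"] = rel
        results[f"plf_spectra_{session}"] = plf
        results[f"relative_spectra_{session}_per_animal"] = rel_an
        results[f"plf_spectra_{session}_per_animal"] = plf_an

    group_stats = _group_stats(band_table, state_table)
    if not group_stats.empty:
        results["group_stats"] = group_stats
    anova_summary, anova_posthoc = _state_anovas(state_table)
    if not anova_summary.empty:
        results["state_anova"] = anova_summary
        results["state_anova_posthoc"] = anova_posthoc

    results["manifest"] = {
        "assrlab_version": __version__,
        "seed": seed_used,
        "analysis_config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(cfg).items()
            if k != "bands"
        },
        "bands": {k: list(v) for k, v in cfg.bands.items()},
        "n_recordings_analyzed": len(analyses),
        "included_channels": {
            a.animal_id: a.included_channels for a in analyses
        },
    }
    make_report(results, out_dir)
    logger.info("report written to %s", out_dir)
    return out_dir
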