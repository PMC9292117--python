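"""Config-driven orchestration: tracks -> profiles -> tables -> partitions -> stats.

Two entry points:

* :func:`run_pipeline` drives the analysis over fragment files (or in-memory
  fragment sets) described by a :class:`RunConfig` -- read, coverage/dyad,
  normalize, merge, correct/mask, window quantification, rankings/partitions,
  statistics -- writing every figure-style product as a TSV plus a manifest.
* :func:`simulate_and_run` generates a full synthetic scenario, runs the same
  analysis surface on it, and scores the results against the planted truth
  with the recovery harness.  This is the single-command demo.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregate import anchor_matrix, average_profile, difference_matrix, \
    dyad_profile, profile_to_frame, sort_rows
from .io import FragmentSet, SampleMeta, read_features, read_fragments, \
    read_genome_layout
from .quantify import decile_bins, fold_change_ranking, half_bins, log2_table, \
    occupancy_table, quartile_sets
from .simulate import ScenarioConfig, build_scenario, recovery_harness, \
    sample_fragments
from .stats import box_summary, mann_whitney, pearson, sector_classify
from .tracks import DyadParams, OccupancyTrack, compute_coverage, \
    compute_dyad_density, correct_background, mask_intervals, \
    merge_replicates, moving_average, normalize_per_chromosome

log = logging.getLogger("ndrchip")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------


def _sha256_bytes(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def _frame_checksum(frame: pd.DataFrame) -> str:
    return _sha256_bytes(frame.to_csv(sep="\t").encode())


@dataclass
class RunManifest:
    config_hash: str
    version: str
    checksums: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    stages: list[str] = field(default_factory=list)

    def record(self, stage: str, name: str, frame: pd.DataFrame):
        if stage not in self.stages:
            self.stages.append(stage)
        self.checksums[name] = _frame_checksum(frame)

    def to_json(self) -> str:
        return json.dumps(
            {"config_hash": self.config_hash, "version": self.version,
             "stages": self.stages, "checksums": self.checksums,
             "warnings": self.warnings}, indent=2)


# ---------------------------------------------------------------------------
# Track building
# ---------------------------------------------------------------------------


def tracks_from_fragments(replicates: list[FragmentSet],
                          dyad_params: DyadParams = DyadParams()) -> OccupancyTrack:
    """Coverage (or dyad density for MNase) per replicate, normalized, merged."""
    per_rep = []
    for frags in replicates:
        if frags.meta.prep == "mnase":
            raw = compute_dyad_density(frags, dyad_params)
        else:
            raw = compute_coverage(frags)
        per_rep.append(normalize_per_chromosome(raw))
    return merge_replicates(per_rep)


# ---------------------------------------------------------------------------
# File-driven pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Sample sheet plus annotation paths and analysis parameters.

    ``samples`` entries are dicts with keys ``path`` (or ``fragments`` for an
    in-memory FragmentSet), ``strain``, ``condition``, ``target``, ``prep``,
    ``replicate``.  ``comparisons`` are (mutant_key, wt_key) pairs over merged
    sample keys ``<target>:<strain>_<condition>``.
    """

    layout_path: str = ""
    features_path: str = ""
    samples: list[dict] = field(default_factory=list)
    comparisons: list[tuple[str, str]] = field(default_factory=list)
    anchor_kind: str = "gcn4_motif"
    flank: int = 100
    dyad: DyadParams = field(default_factory=DyadParams)
    outdir: str | None = None

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            blob = yaml.safe_load(fh)
        dyad = DyadParams(**blob.pop("dyad", {}))
        comparisons = [tuple(c) for c in blob.pop("comparisons", [])]
        return RunConfig(dyad=dyad, comparisons=comparisons, **blob)

    def sample_key(self, entry: dict) -> str:
        return f"{entry['target']}:{entry['strain']}_{entry['condition']}"

    def validate(self):
        keys = {self.sample_key(e) for e in self.samples}
        for mutant, wt in self.comparisons:
            for k in (mutant, wt):
                if k not in keys:
                    raise PipelineError("validate",
                                        f"comparison references undeclared sample {k!r}")
        for e in self.samples:
            if "path" not in e and "fragments" not in e:
                raise PipelineError("validate", f"sample entry missing path: {e}")


def run_pipeline(config: RunConfig) -> tuple[dict, RunManifest]:
    """Execute the full stage order on a validated config; returns outputs + manifest."""
    config.validate()
    manifest = RunManifest(
        config_hash=_sha256_bytes(repr(config).encode()), version=__version__)
    outputs: dict = {}

    try:
        layout = read_genome_layout(config.layout_path)
        features = read_features(config.features_path, layout)
    except Exception as exc:
        raise PipelineError("read_annotations", str(exc)) from exc

    # read fragments and group replicates by merged sample key
    groups: dict[str, list[FragmentSet]] = {}
    for entry in config.samples:
        meta = SampleMeta(strain=entry["strain"], condition=entry["condition"],
                          target=entry["target"], prep=entry.get("prep", "sonicated"),
                          replicate=entry.get("replicate", "rep1"))
        try:
            frags = entry.get("fragments") or read_fragments(entry["path"], layout, meta)
        except Exception as exc:
            raise PipelineError("read_fragments", f"{entry}: {exc}") from exc
        groups.setdefault(config.sample_key(entry), []).append(frags)
    log.info("read %d samples into %d merged groups",
             len(config.samples), len(groups))

    tracks = {}
    for key, reps in groups.items():
        try:
            tracks[key] = tracks_from_fragments(reps, config.dyad)
        except Exception as exc:
            raise PipelineError("tracks", f"{key}: {exc}") from exc
    outputs["tracks"] = tracks

    anchors = features.of_kind(config.anchor_kind)
    if len(anchors) == 0:
        raise PipelineError("aggregate",
                            f"no features of anchor kind {config.anchor_kind!r}")
    table = occupancy_table(tracks, anchors, flank=config.flank)
    outputs["window_table"] = table
    manifest.record("quantify", "window_table", table)

    outputs["profiles"] = {
        key: profile_to_frame(average_profile(
            anchor_matrix(track, anchors, flank=max(config.flank, 500))))
        for key, track in tracks.items()
    }
    for key, frame in outputs["profiles"].items():
        manifest.record("aggregate", f"profile_{key}", frame)

    comparisons_rows = []
    partitions = {}
    for mutant, wt in config.comparisons:
        ranking = fold_change_ranking(table, mutant, wt)
        sets = quartile_sets(list(ranking.index))
        partitions[(mutant, wt)] = sets
        for label in sets.order:
            members = sets.members(label)
            res = mann_whitney(table.loc[members, mutant], table.loc[members, wt],
                               f"{mutant}|{label}", f"{wt}|{label}")
            comparisons_rows.append(res.as_row())
        manifest.record("partition", f"sets_{mutant}_vs_{wt}", sets.to_frame())
    outputs["partitions"] = partitions
    stats_frame = pd.DataFrame(comparisons_rows)
    outputs["comparisons"] = stats_frame
    if len(stats_frame):
        manifest.record("stats", "comparisons", stats_frame)

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "window_table.tsv", sep="\t")
        stats_frame.to_csv(outdir / "comparisons.tsv", sep="\t", index=False)
        for key, frame in outputs["profiles"].items():
            frame.to_csv(outdir / f"profile_{key.replace(':', '_')}.tsv",
                         sep="\t", index=False)
        (outdir / "manifest.json").write_text(manifest.to_json())
    return outputs, manifest


# ---------------------------------------------------------------------------
# Synthetic demo: simulate, analyze, score against the planted truth
# ---------------------------------------------------------------------------

#: The demo's sample registry: (target, strain, condition, prep).
DEMO_SAMPLES = [
    ("Gcn4", "WT", "U", "sonicated"),
    ("Gcn4", "WT", "I", "sonicated"),
    ("Gcn4", "snf2", "I", "sonicated"),
    ("Gcn4", "sth1", "I", "sonicated"),
    ("Gcn4", "snf2_sth1", "I", "sonicated"),
    ("Gcn4", "ino80", "I", "sonicated"),
    ("H3", "WT", "U", "sonicated"),
    ("H3", "WT", "I", "sonicated"),
    ("H3", "snf2", "I", "sonicated"),
    ("H3", "sth1", "I", "sonicated"),
    ("H3", "snf2_sth1", "I", "sonicated"),
    ("H3", "WT", "U", "mnase"),
    ("H3", "WT", "I", "mnase"),
    ("TBP", "WT", "U", "sonicated"),
    ("TBP", "WT", "I", "sonicated"),
    ("TBP", "snf2_sth1", "I", "sonicated"),
    ("Rpb3", "WT", "U", "sonicated"),
    ("Rpb3", "WT", "I", "sonicated"),
    ("Rpb3", "snf2_sth1", "I", "sonicated"),
    ("Snf2-myc", "WT", "I", "sonicated"),
    ("untagged", "WT", "I", "sonicated"),
]


def _merged_key(target: str, strain: str, condition: str, prep: str) -> str:
    base = f"{target}:{strain}_{condition}"
    return base + ("-mnase" if prep == "mnase" else "")


def simulate_and_run(scenario: ScenarioConfig | None = None, seed: int = 0,
                     n_fragments: int | None = None,
                     n_replicates: int | None = None,
                     outdir: str | None = None) -> dict:
    """Generate the demo scenario, run the full analysis, score the recovery.

    Returns a dict of every figure-style product (tables, profiles,
    partitions, statistics) plus ``truth``, ``report`` (the recovery report)
    and ``manifest``.
    """
    cfg = scenario or ScenarioConfig()
    n = cfg.n_fragments if n_fragments is None else int(n_fragments)
    reps = cfg.n_replicates if n_replicates is None else int(n_replicates)

    truth = build_scenario(cfg, seed)
    manifest = RunManifest(config_hash=_sha256_bytes(truth.to_json().encode()),
                           version=__version__)
    out: dict = {"truth": truth, "n_fragments": n}

    # --- stage: simulate + tracks -----------------------------------------
    tracks: dict[str, OccupancyTrack] = {}
    for target, strain, condition, prep in DEMO_SAMPLES:
        frag_reps = [
            sample_fragments(truth, target, strain, condition, prep,
                             n_fragments=n, replicate=f"rep{r + 1}")
            for r in range(reps)
        ]
        key = _merged_key(target, strain, condition, prep)
        tracks[key] = tracks_from_fragments(frag_reps)
        if key == "TBP:WT_I":
            # summit localization track: sonicated coverage is flat within
            # +-(min fragment length)/2 of a point source, so summits are
            # located from fragment-midpoint density instead (smoothed below)
            lo, hi = cfg.sonicated_range
            mid_params = DyadParams(lo, hi, 31)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # midpoint use is intentional
                tracks["TBP:WT_I:midpoints"] = merge_replicates([
                    normalize_per_chromosome(compute_dyad_density(f, mid_params))
                    for f in frag_reps
                ])
    log.info("built %d merged tracks (%d fragments x %d replicates each)",
             len(tracks), n, reps)

    # --- stage: correct / mask --------------------------------------------
    tracks["Snf2-myc:WT_I:corrected"] = correct_background(
        tracks["Snf2-myc:WT_I"], tracks["untagged:WT_I"])
    tdna = truth.tdna_flank_table()
    for key in ("TBP:WT_U", "TBP:WT_I", "TBP:snf2_sth1_I"):
        tracks[key + ":masked"] = mask_intervals(tracks[key], tdna)
    out["tracks"] = tracks

    # --- stage: window quantification --------------------------------------
    motifs5 = truth.motif_table("5prime")
    gcn4_keys = {k: tracks[k] for k in tracks if k.startswith("Gcn4:")}
    h3_keys = {k: tracks[k] for k in tracks
               if k.startswith("H3:") and not k.endswith("-mnase")}
    out["gcn4_window"] = occupancy_table(gcn4_keys, motifs5, flank=100)
    out["h3_window"] = occupancy_table(h3_keys, motifs5, flank=100)
    summits = truth.tbp_summit_table()
    out["tbp_window"] = occupancy_table(
        {k: tracks[k + ":masked"] for k in ("TBP:WT_U", "TBP:WT_I",
                                            "TBP:snf2_sth1_I")},
        summits, flank=100)
    cds = truth.cds_table()
    out["rpb3_cds"] = occupancy_table(
        {k: tracks[k] for k in ("Rpb3:WT_U", "Rpb3:WT_I", "Rpb3:snf2_sth1_I")},
        cds, flank=None)
    out["myc_window"] = occupancy_table(
        {"Snf2-myc:WT_I:corrected": tracks["Snf2-myc:WT_I:corrected"]},
        motifs5, flank=100)
    manifest.record("quantify", "gcn4_window", out["gcn4_window"])
    manifest.record("quantify", "h3_window", out["h3_window"])
    manifest.record("quantify", "tbp_window", out["tbp_window"])

    # --- stage: profiles / matrices / difference maps ----------------------
    flank = 1000
    gcn4_wt = anchor_matrix(tracks["Gcn4:WT_I"], motifs5, flank)
    gcn4_dbl = anchor_matrix(tracks["Gcn4:snf2_sth1_I"], motifs5, flank)
    out["gcn4_profile_wt_i"] = average_profile(gcn4_wt)
    out["gcn4_diff_matrix"] = difference_matrix(gcn4_dbl, gcn4_wt)
    out["dyad_profile"] = dyad_profile(tracks["H3:WT_U-mnase"], motifs5,
                                       flank=600, span=31, orient_by_strand=True)
    out["dyad_profile_induced"] = dyad_profile(tracks["H3:WT_I-mnase"], motifs5,
                                               flank=600, span=31,
                                               orient_by_strand=True)
    out["tbp_coverage_profile"] = average_profile(anchor_matrix(
        tracks["TBP:WT_I:masked"], motifs5, flank=600, orient_by_strand=True))
    tbp_mid = average_profile(anchor_matrix(
        tracks["TBP:WT_I:midpoints"], motifs5, flank=600, orient_by_strand=True))
    tbp_mid.mean = moving_average(tbp_mid.mean, 31)
    out["tbp_profile"] = tbp_mid

    # --- stage: rankings, partitions, statistics ---------------------------
    ranking = fold_change_ranking(out["gcn4_window"],
                                  "Gcn4:snf2_sth1_I", "Gcn4:WT_I")
    out["ranking"] = ranking
    sets = quartile_sets(list(ranking.index))
    out["sets"] = sets
    manifest.record("partition", "quartile_sets", sets.to_frame())

    # sorted difference map shares the ranking's row order (three-panel style)
    key_order = {fid: i for i, fid in enumerate(ranking.index)}
    out["gcn4_diff_matrix_sorted"] = sort_rows(out["gcn4_diff_matrix"], key_order)

    rows = []
    for label in sets.order:
        members = sets.members(label)
        for mutant in ("Gcn4:snf2_I", "Gcn4:sth1_I", "Gcn4:snf2_sth1_I",
                       "Gcn4:ino80_I"):
            res = mann_whitney(out["gcn4_window"].loc[members, mutant],
                               out["gcn4_window"].loc[members, "Gcn4:WT_I"],
                               f"{mutant}|{label}", f"WT_I|{label}")
            box = box_summary(np.log2(out["gcn4_window"].loc[members, mutant]))
            rows.append({**res.as_row(), "set": label, "box_median": box.median,
                         "box_notch": box.notch})
    out["set_stats"] = pd.DataFrame(rows)
    manifest.record("stats", "set_stats", out["set_stats"])

    # sector scatter: Gcn4 change vs H3 change in the double mutant
    lg = np.log2(out["gcn4_window"]["Gcn4:snf2_sth1_I"]
                 / out["gcn4_window"]["Gcn4:WT_I"])
    lh = np.log2(out["h3_window"]["H3:snf2_sth1_I"] / out["h3_window"]["H3:WT_I"])
    out["sector"] = sector_classify(lg.to_numpy(), lh.to_numpy())

    # remodeler recruitment vs activator occupancy
    log2_gcn4 = log2_table(out["gcn4_window"], ["Gcn4:WT_I"])
    out["myc_gcn4_pearson"] = pearson(log2_gcn4["log2_Gcn4:WT_I"],
                                      out["myc_window"]["Snf2-myc:WT_I:corrected"])

    # expression deciles and TBP halves
    rpb3_rank = out["rpb3_cds"]["Rpb3:WT_U"].sort_values(ascending=False)
    out["deciles"] = decile_bins(list(rpb3_rank.index), k=10)
    tbp_rank = out["tbp_window"]["TBP:WT_I"].sort_values(ascending=False)
    out["tbp_halves"] = half_bins(list(tbp_rank.index), "High_TBP", "Low_TBP")

    # --- stage: recovery scoring -------------------------------------------
    out["report"] = recovery_harness(truth, {
        "gcn4_window": out["gcn4_window"], "h3_window": out["h3_window"],
        "dyad_profile": out["dyad_profile"], "tbp_profile": out["tbp_profile"],
        "n_fragments": n,
    })
    manifest.record("recovery", "report", out["report"].to_frame())
    out["manifest"] = manifest

    if outdir:
        path = Path(outdir)
        path.mkdir(parents=True, exist_ok=True)
        (path / "scenario.json").write_text(truth.to_json())
        out["gcn4_window"].to_csv(path / "gcn4_window.tsv", sep="\t")
        out["h3_window"].to_csv(path / "h3_window.tsv", sep="\t")
        out["tbp_window"].to_csv(path / "tbp_window.tsv", sep="\t")
        out["rpb3_cds"].to_csv(path / "rpb3_cds.tsv", sep="\t")
        out["set_stats"].to_csv(path / "set_stats.tsv", sep="\t", index=False)
        sets.to_frame().to_csv(path / "quartile_sets.tsv", sep="\t", index=False)
        profile_to_frame(out["dyad_profile"]).to_csv(
            path / "dyad_profile.tsv", sep="\t", index=False)
        profile_to_frame(out["tbp_profile"]).to_csv(
            path / "tbp_profile.tsv", sep="\t", index=False)
        out["report"].to_frame().to_csv(path / "recovery_report.tsv", sep="\t",
                                        index=False)
        (path / "manifest.json").write_text(manifest.to_json())
    return out
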