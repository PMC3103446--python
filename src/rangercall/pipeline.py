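"""End-to-end orchestration: presets, configuration, parallel execution.

The pipeline is partitioned by chromosome — peak calls on different
chromosomes are independent except for the genome-wide steps (control
scaling and Benjamini-Hochberg FDR), which gather per-chromosome results
centrally before filtering.  Output is byte-identical for any worker
count, which is tested, not assumed.
"""

from __future__ import annotations

import dataclasses
import os
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass
from typing import Optional

from . import alignment_io, coverage, region_caller, summit_caller
from .alignment_io import ChromTable, ParseStats
from .region_caller import CandidateRegion
from .summit_caller import SummitConfig

MODES = ("region", "resolution")
WIGGLE_CHOICES = ("off", "plain", "gzip")


class ConfigError(ValueError):
    """Invalid run-time configuration."""


@dataclass
class CallerConfig:
    """All tunables of one peak-calling run."""

    mode: str = "region"
    ext_len: int = 200
    fdr_cutoff: float = 0.01
    delta: float = 0.5
    smooth_window: int = 31
    max_gap: int = 100
    thr_p: float = 1e-4
    min_rel_height: float = 0.0
    workers: int = 1
    wiggle: str = "off"
    seed: int = 0
    chrom_table_path: Optional[str] = None
    format: str = "auto"
    lenient: bool = False
    max_dup: int = 0  # 0 = no duplicate filtering
    bin_size: int = 10_000

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.wiggle not in WIGGLE_CHOICES:
            raise ConfigError(
                f"wiggle must be one of {WIGGLE_CHOICES}, got {self.wiggle!r}"
            )
        if self.ext_len < 1:
            raise ConfigError(f"ext_len must be >= 1, got {self.ext_len}")
        if not 0 <= self.fdr_cutoff <= 1:
            raise ConfigError(f"fdr_cutoff must be in [0,1], got {self.fdr_cutoff}")
        if not 0 < self.delta < 1:
            raise ConfigError(f"delta must be in (0,1), got {self.delta}")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ConfigError(
                f"smooth_window must be odd and >= 1, got {self.smooth_window}"
            )
        if self.max_gap < 0:
            raise ConfigError(f"max_gap must be >= 0, got {self.max_gap}")
        if not 0 < self.thr_p < 1:
            raise ConfigError(f"thr_p must be in (0,1), got {self.thr_p}")
        if not 0 <= self.min_rel_height <= 1:
            raise ConfigError(
                f"min_rel_height must be in [0,1], got {self.min_rel_height}"
            )
        if self.workers < 1:
            raise ConfigError(f"workers must be >= 1, got {self.workers}")

    def summit_config(self) -> SummitConfig:
        return SummitConfig(
            delta=self.delta,
            smooth_window=self.smooth_window,
            min_rel_height=self.min_rel_height,
        )


# Preset parameter sets: broad histone-mark domains ("region") call with a
# shallow delta and heavy smoothing; punctate transcription-factor sites
# ("resolution") with a steep delta and minimal smoothing.
_PRESETS = {
    "region": {"delta": 0.5, "smooth_window": 31},
    "resolution": {"delta": 0.8, "smooth_window": 5},
}


def apply_preset(mode: str) -> CallerConfig:
    """Default configuration for a mode; shared defaults fill the rest."""
    if mode not in _PRESETS:
        raise ConfigError(f"unknown mode {mode!r}; expected one of {MODES}")
    return CallerConfig(mode=mode, **_PRESETS[mode])


# config-file key -> (CallerConfig field, parser)
def _parse_bool(v: str) -> bool:
    lv = v.lower()
    if lv in ("1", "true", "yes", "on"):
        return True
    if lv in ("0", "false", "no", "off"):
        return False
    raise ValueError(f"not a boolean: {v!r}")


_CONFIG_KEYS = {
    "mode": ("mode", str),
    "ext": ("ext_len", int),
    "ext_len": ("ext_len", int),
    "fdr": ("fdr_cutoff", float),
    "fdr_cutoff": ("fdr_cutoff", float),
    "delta": ("delta", float),
    "smooth": ("smooth_window", int),
    "smooth_window": ("smooth_window", int),
    "max_gap": ("max_gap", int),
    "thr_p": ("thr_p", float),
    "min_rel_height": ("min_rel_height", float),
    "workers": ("workers", int),
    "wiggle": ("wiggle", str),
    "seed": ("seed", int),
    "genome": ("chrom_table_path", str),
    "chrom_table_path": ("chrom_table_path", str),
    "format": ("format", str),
    "lenient": ("lenient", _parse_bool),
    "max_dup": ("max_dup", int),
    "bin_size": ("bin_size", int),
}


def load_config(path: str) -> dict:
    """Parse a ``key = value`` configuration file into a partial config dict.

    Only keys present in the file are returned; the caller applies the
    precedence flags > file > preset.  Unknown keys and unparsable
    values are fatal, with the line number.
    """
    partial: dict = {}
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in _CONFIG_KEYS:
                raise ConfigError(f"{path}:{lineno}: unknown configuration key {key!r}")
            field_name, parse = _CONFIG_KEYS[key]
            try:
                partial[field_name] = parse(raw)
            except ValueError as exc:
                raise ConfigError(
                    f"{path}:{lineno}: bad value {raw!r} for {key!r}: {exc}"
                ) from exc
    return partial


def build_config(
    mode: str = "region",
    config_file: Optional[str] = None,
    overrides: Optional[dict] = None,
) -> CallerConfig:
    """Compose the effective configuration: flags > config file > preset."""
    values = dataclasses.asdict(apply_preset(mode))
    if config_file is not None:
        file_values = load_config(config_file)
        mode = file_values.get("mode", mode)
        values.update(dataclasses.asdict(apply_preset(mode)))
        values.update(file_values)
    if overrides:
        new_mode = overrides.get("mode")
        if new_mode is not None and new_mode != values["mode"]:
            preset = dataclasses.asdict(apply_preset(new_mode))
            for k in ("delta", "smooth_window"):
                if overrides.get(k) is None:
                    values[k] = preset[k]
            values["mode"] = new_mode
        values.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return CallerConfig(**values)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def _summit_stage(args) -> list[CandidateRegion]:
    depth, regions, summit_cfg = args
    return [summit_caller.call_summits(r, depth, summit_cfg) for r in regions]


def call_peaks(
    treat_profile: coverage.CoverageProfile,
    ctrl_profile: Optional[coverage.CoverageProfile],
    config: CallerConfig,
) -> tuple[list[CandidateRegion], dict]:
    """Regions + summits from coverage profiles, parallel over chromosomes."""
    executor = None
    pool_map = map
    if config.workers > 1:
        executor = ProcessPoolExecutor(max_workers=config.workers)
        pool_map = executor.map
    try:
        regions, fit, info = region_caller.call_regions(
            treat_profile,
            ctrl_profile,
            fdr_cutoff=config.fdr_cutoff,
            thr_p=config.thr_p,
            max_gap=config.max_gap,
            bin_size=config.bin_size,
            pool_map=pool_map,
        )
        by_chrom: dict[str, list[CandidateRegion]] = {}
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append(r)
        summit_cfg = config.summit_config()
        tasks = [
            (treat_profile[chrom], by_chrom[chrom], summit_cfg)
            for chrom in sorted(by_chrom)
        ]
        called: list[CandidateRegion] = []
        for chunk in pool_map(_summit_stage, tasks):
            called.extend(chunk)
    finally:
        if executor is not None:
            executor.shutdown()
    info["scaling"] = dataclasses.asdict(fit) if fit is not None else None
    info["n_summits"] = sum(len(r.summits) for r in called)
    return called, info


def run(
    treatment_path: str,
    control_path: Optional[str],
    config: CallerConfig,
    output_prefix: str,
) -> dict:
    """File-to-file peak calling; returns the run log as a dict.

    Outputs: ``<prefix>_regions.bed`` (one row per region),
    ``<prefix>_summits.txt`` (one row per summit in resolution mode,
    one per region otherwise), optional ``<prefix>.wig[.gz]`` coverage
    tracks, and ``<prefix>.log``.
    """
    log: dict = {"config": dataclasses.asdict(config)}

    t_stats = ParseStats()
    treat_reads = list(
        alignment_io.parse_alignments(
            treatment_path, config.format, config.lenient, t_stats
        )
    )
    if not treat_reads:
        raise ValueError(f"no mapped reads parsed from {treatment_path}")
    ctrl_reads = None
    c_stats = ParseStats()
    if control_path is not None:
        ctrl_reads = list(
            alignment_io.parse_alignments(
                control_path, config.format, config.lenient, c_stats
            )
        )
    log["treatment"] = {"parsed": t_stats.n_parsed, "skipped": t_stats.n_skipped}
    if control_path is not None:
        log["control"] = {"parsed": c_stats.n_parsed, "skipped": c_stats.n_skipped}

    if config.max_dup > 0:
        treat_reads = list(coverage.max_duplicate_filter(treat_reads, config.max_dup))
        if ctrl_reads is not None:
            ctrl_reads = list(
                coverage.max_duplicate_filter(ctrl_reads, config.max_dup)
            )

    if config.chrom_table_path:
        table = alignment_io.load_chrom_table(config.chrom_table_path)
    else:
        all_reads = treat_reads + (ctrl_reads or [])
        table = alignment_io.derive_chrom_table(all_reads, slack=config.ext_len)
    log["chrom_table"] = {
        "provenance": table.provenance,
        "n_chroms": len(table.lengths),
        "total_length": table.total_length,
    }

    treat_profile = coverage.build_coverage(treat_reads, config.ext_len, table)
    ctrl_profile = (
        coverage.build_coverage(ctrl_reads, config.ext_len, table)
        if ctrl_reads is not None
        else None
    )
    log["coverage"] = {
        "treat_fragments": treat_profile.n_fragments,
        "treat_dropped": treat_profile.n_dropped,
    }

    regions, info = call_peaks(treat_profile, ctrl_profile, config)
    log["calling"] = info

    regions_path = f"{output_prefix}_regions.bed"
    summits_path = f"{output_prefix}_summits.txt"
    alignment_io.write_peaks(regions, regions_path, mode="region")
    _write_summits(regions, summits_path, config.mode)
    log["outputs"] = [regions_path, summits_path]

    if config.wiggle != "off":
        gz = config.wiggle == "gzip"
        wig_path = f"{output_prefix}.wig" + (".gz" if gz else "")
        alignment_io.write_wiggle(treat_profile, wig_path, compress=gz)
        log["outputs"].append(wig_path)

    _write_log(log, f"{output_prefix}.log")
    return log


def _write_summits(regions: list[CandidateRegion], path: str, mode: str) -> None:
    with open(path, "wt") as fh:
        fh.write("#chrom\tsummit_start\tsummit_end\tregion\theight\tq_value\n")
        for reg in regions:
            summits = reg.summits
            if mode != "resolution" and summits:
                summits = [max(summits, key=lambda s: (s.height, -s.pos))]
            for s in summits:
                fh.write(
                    f"{reg.chrom}\t{s.pos}\t{s.pos + 1}\t{reg.name}\t"
                    f"{s.height:.6g}\t{reg.q_value:.6g}\n"
                )


def _write_log(log: dict, path: str) -> None:
    import json

    with open(path, "wt") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")


def ensure_writable(prefix: str) -> None:
    d = os.path.dirname(os.path.abspath(prefix))
    if not os.path.isdir(d):
        raise ValueError(f"output directory does not exist: {d}")
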