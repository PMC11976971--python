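"""Run orchestration: configuration, staged execution, manifests, logging.

Each run executes prep -> collapse -> call -> summarise (RACE) or
parse -> filter -> classify -> flank/adjacency (SNV screen), writes
tab-separated result tables, and records a machine-readable manifest listing
inputs, parameters and a SHA-256 digest of every output file, so reruns can
be verified byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import __version__
from .construct import ConstructAnnotation, demo_construct, load_construct
from .endcall import (DEFAULT_WINDOW_3P, DEFAULT_WINDOW_5P, cap_fraction,
                      call_3prime_end, call_5prime_end, collapse_top_n,
                      end_distribution, modification_spectrum)
from .readprep import prep_reads
from .simulate import read_fastq
from .snv import (load_transcripts_genbank, parse_variant_summary,
                  screen_summary, screen_variants, targetable_table)

log = logging.getLogger("racemap")


class PipelineError(RuntimeError):
    """A stage failure carrying the stage name (and record id if known)."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RaceConfig:
    """Parameters of one RACE end-mapping run."""

    fastq: str
    mode: str = "3p"  # "3p" or "5p"
    construct_fasta: Optional[str] = None
    construct_yaml: Optional[str] = None
    adapter3: Optional[str] = None
    adapter5: Optional[str] = None
    min_len: int = 20
    q: int = 30
    p: float = 95.0
    n_random_nt: int = 4
    top_n: int = 20
    min_anchor: int = 15
    window: Optional[Tuple[int, int]] = None
    sample: str = "sample"
    out_dir: str = "racemap_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("3p", "5p"):
            raise ValueError("mode must be '3p' or '5p'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RaceConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        doc.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "window" in doc and doc["window"] is not None:
            doc["window"] = tuple(doc["window"])
        return cls(**doc)

    def construct(self) -> ConstructAnnotation:
        if self.construct_fasta and self.construct_yaml:
            return load_construct(self.construct_fasta, self.construct_yaml)
        return demo_construct()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out_dir: Path, inputs: Dict, params: Dict, seed: int) -> Path:
    outputs = {p.name: _sha256(p) for p in sorted(out_dir.iterdir())
               if p.is_file() and p.name != "manifest.json"}
    manifest = {"tool": "racemap", "version": __version__, "seed": seed,
                "inputs": inputs, "parameters": params, "outputs": outputs}
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _distribution_frame(sample: str, dist) -> pd.DataFrame:
    row = {str(k): v for k, v in dist.proportions.items()}
    df = pd.DataFrame([row], index=[sample])
    df.index.name = "construct"
    return df


def run_race_pipeline(cfg: RaceConfig) -> Dict[str, Path]:
    """Execute prep -> collapse -> call -> summarise; returns output paths.

    Offsets in the distribution tables use the biology convention stated in
    the headers: 5' offset 0 = the +1 site, 3' offset 0 = the last annotated
    crRNA base.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    construct = cfg.construct()

    try:
        reads = read_fastq(cfg.fastq)
    except FileNotFoundError as exc:
        raise PipelineError("prep", f"FASTQ not found: {exc}") from exc
    if not reads:
        raise PipelineError("prep", f"no reads in {cfg.fastq}")
    log.info("prep: %d reads in", len(reads))

    trimmed, stats = prep_reads(
        reads, adapter3=cfg.adapter3, adapter5=cfg.adapter5, min_len=cfg.min_len,
        q=cfg.q, p=cfg.p, n_random_nt=cfg.n_random_nt)
    if not trimmed:
        raise PipelineError("prep", "no reads survived preprocessing")
    log.info("prep: %d reads kept", stats.n_out)

    ranked = collapse_top_n([t.insert for t in trimmed], n=cfg.top_n)
    log.info("collapse: %d ranked sequences", len(ranked))

    if cfg.mode == "3p":
        window = cfg.window or DEFAULT_WINDOW_3P
        calls = [(call_3prime_end(r.insert, construct, min_anchor=cfg.min_anchor),
                  float(r.count)) for r in ranked]
    else:
        window = cfg.window or DEFAULT_WINDOW_5P
        calls = [(call_5prime_end(r.insert, construct, min_anchor=cfg.min_anchor),
                  float(r.count)) for r in ranked]
    n_assigned = sum(1 for c, _ in calls if c is not None)
    log.info("call: %d/%d ranked sequences assigned", n_assigned, len(calls))

    dist = end_distribution(calls, window=window)
    spec_table = modification_spectrum(calls)

    outputs: Dict[str, Path] = {}
    dist_name = "end3_distribution.tsv" if cfg.mode == "3p" else "end5_distribution.tsv"
    dist_path = out_dir / dist_name
    with open(dist_path, "w") as fh:
        origin = ("offset 0 = last annotated crRNA base" if cfg.mode == "3p"
                  else "offset 0 = +1 site")
        fh.write(f"# end-position proportions; {origin}\n")
        _distribution_frame(cfg.sample, dist).to_csv(fh, sep="\t")
    outputs["distribution"] = dist_path

    mod_path = out_dir / "modifications.tsv"
    _distribution_frame(cfg.sample, spec_table).to_csv(mod_path, sep="\t")
    outputs["modifications"] = mod_path

    if cfg.mode == "5p":
        cap = cap_fraction(calls)
        cap_path = out_dir / "cap_fraction.tsv"
        pd.DataFrame([{
            "construct": cfg.sample, "cap_fraction": cap.estimate,
            "ci_low": cap.ci_low, "ci_high": cap.ci_high,
            "weight_capped": cap.weight_capped, "weight_uncapped": cap.weight_uncapped,
        }]).to_csv(cap_path, sep="\t", index=False)
        outputs["cap_fraction"] = cap_path

    stats_path = out_dir / "prep_stats.tsv"
    pd.DataFrame(stats.as_rows(), columns=["step", "reads"]).to_csv(
        stats_path, sep="\t", index=False)
    outputs["prep_stats"] = stats_path

    params = {k: v for k, v in dataclasses.asdict(cfg).items() if k != "fastq"}
    outputs["manifest"] = _write_manifest(out_dir, {"fastq": str(cfg.fastq)},
                                          params, cfg.seed)
    return outputs


@dataclass
class ScreenConfig:
    """Parameters of one SNV-screen run."""

    variant_table: str
    transcripts: str
    pathogenic_mode: str = "strict"
    half_window: int = 30
    adjacency_nt: int = 30
    sweep: Optional[List[int]] = None  # e.g. [10, 20, 30, 50]
    dedup: bool = True
    out_dir: str = "racemap_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "ScreenConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        doc.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


def run_snv_screen(cfg: ScreenConfig) -> Dict[str, Path]:
    """Execute the variant screen; returns output paths."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for path, stage in ((cfg.variant_table, "parse-variants"),
                        (cfg.transcripts, "load-transcripts")):
        if not Path(path).exists():
            raise PipelineError(stage, f"input not found: {path}")

    records = parse_variant_summary(cfg.variant_table)
    transcripts = load_transcripts_genbank(cfg.transcripts)
    log.info("screen: %d records, %d transcripts", len(records), len(transcripts))

    windows = cfg.sweep if cfg.sweep else [cfg.adjacency_nt]
    summary = screen_summary(records, transcripts, pathogenic_mode=cfg.pathogenic_mode,
                             half_window=cfg.half_window, adjacency_windows=windows,
                             dedup=cfg.dedup)
    hits, skip_report = screen_variants(records, transcripts,
                                        pathogenic_mode=cfg.pathogenic_mode,
                                        half_window=cfg.half_window,
                                        adjacency_nt=cfg.adjacency_nt,
                                        dedup=cfg.dedup)

    outputs: Dict[str, Path] = {}
    summary_path = out_dir / "screen_summary.tsv"
    summary.to_csv(summary_path, sep="\t", index=False)
    outputs["summary"] = summary_path

    hits_path = out_dir / "targetable_variants.tsv"
    targetable_table(hits).to_csv(hits_path, sep="\t", index=False)
    outputs["targetable"] = hits_path

    skip_path = out_dir / "skip_report.tsv"
    skip_report.to_csv(skip_path, sep="\t", index=False)
    outputs["skips"] = skip_path

    params = {k: v for k, v in dataclasses.asdict(cfg).items()
              if k not in ("variant_table", "transcripts")}
    outputs["manifest"] = _write_manifest(
        out_dir, {"variant_table": str(cfg.variant_table),
                  "transcripts": str(cfg.transcripts)}, params, cfg.seed)
    return outputs
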