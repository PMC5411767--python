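"""Three-stage pipeline: correction -> trimming -> assembly.

Each stage is independently runnable and begins by (re)computing overlaps
for its own inputs: correction uses sketch-estimated overlaps (no gapped
alignment yet), trimming and assembly confirm candidates with gapped
alignments. Assembly additionally runs overlap error adjustment before
graph construction, then contig consensus and GFA output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import adjust as adjust_mod
from . import assemble as assemble_mod
from . import consensus as consensus_mod
from . import correct as correct_mod
from . import trim as trim_mod
from .config import PipelineConfig
from .overlap import Overlap, overlap_read_set
from .sketch import TfIdfParams, count_kmers
from .store import OverlapStore, build_store_from_overlaps

log = logging.getLogger("miniolc.pipeline")


def _params(cfg: PipelineConfig) -> TfIdfParams:
    return TfIdfParams(a=cfg.idf_a, idf_max=cfg.idf_max, tf_cap=cfg.tf_cap,
                       cutoff_interpretation=cfg.cutoff_interpretation)


def compute_overlaps(
    reads: list[tuple[str, str]],
    cfg: PipelineConfig,
    confirm: bool,
    corrected: bool,
) -> list[Overlap]:
    """All-vs-all overlaps for a stage's input reads."""
    if len(reads) < 2:
        return []
    spectrum = count_kmers(reads, cfg.k, cfg.spectrum_cutoff)
    s = cfg.sketch_size_corrected if corrected else cfg.sketch_size
    max_err = 0.25 if corrected else 0.5
    return overlap_read_set(
        reads, spectrum, _params(cfg), s=s, k=cfg.k, seed=cfg.seed,
        bottom_size=cfg.bottom_size, min_slot_matches=cfg.min_slot_matches,
        min_overlap=cfg.min_overlap, confirm=confirm,
        weighting=cfg.weighting, max_kmer_count=cfg.max_kmer_count,
        max_error=max_err,
    )


def stage_correct(reads, cfg: PipelineConfig, rounds: int | None = None):
    """Correction stage: one or more chained correction rounds."""
    rounds = rounds if rounds is not None else cfg.cor_rounds
    return correct_mod.iterate_correction(reads, cfg, rounds)


def stage_trim(corrected, cfg: PipelineConfig):
    """Trimming stage: gapped-alignment overlaps, depth/error/length rule,
    hairpin and chimera detection."""
    overlaps = compute_overlaps(corrected, cfg, confirm=True, corrected=True)
    store = build_store_from_overlaps(overlaps,
                                      known_reads={r for r, _ in corrected})
    return trim_mod.trim_reads(corrected, store, cfg)


@dataclass
class AssemblyOutput:
    contigs: list
    model: assemble_mod.ErrorModel
    gfa: str
    store: OverlapStore
    edits: dict = field(default_factory=dict)
    links: list = field(default_factory=list)


def stage_assemble(trimmed, cfg: PipelineConfig) -> AssemblyOutput:
    """Assembly stage: overlap, error adjustment, graph, consensus, GFA."""
    seqs = dict(trimmed)
    overlaps = compute_overlaps(trimmed, cfg, confirm=True, corrected=True)
    store = build_store_from_overlaps(overlaps, known_reads=set(seqs))
    store, edits = adjust_mod.adjust_store(trimmed, store, cfg)
    result = assemble_mod.assemble(trimmed, store, cfg)
    # consensus evidence uses temporary copies with the vote-detected
    # sequencing errors resolved; residual errors on corrected reads are
    # correlated (shared correction evidence), so the per-read vote across
    # all partners removes more error than column voting at consensus time
    eseqs = {rid: adjust_mod.apply_edits(seq, edits.get(rid, []))
             for rid, seq in trimmed}
    consensus_mod.consensus_all(
        [c for c in result.contigs if c.cls in ("contig", "repeat", "bubble")],
        eseqs)
    gfa = assemble_mod.emit_gfa(
        [c for c in result.contigs if c.cls in ("contig", "repeat", "bubble")],
        result.links)
    return AssemblyOutput(contigs=result.contigs, model=result.model,
                          gfa=gfa, store=store, edits=edits,
                          links=result.links)


def run_pipeline(reads, cfg: PipelineConfig, rounds: int | None = None):
    """correction -> trimming -> assembly on raw reads."""
    corrected = stage_correct(reads, cfg, rounds)
    trimmed, _ranges = stage_trim(corrected, cfg)
    return stage_assemble(trimmed, cfg)


# ------------------------------------------------------------------ reporting

def nx_length(lengths: list[int], frac: float, total: int | None = None) -> int:
    """N50-style statistic: largest L such that contigs >= L sum to
    frac * total (total = assembly size for N50, genome size for NG50)."""
    if not lengths:
        return 0
    lengths = sorted(lengths, reverse=True)
    total = total if total is not None else sum(lengths)
    acc = 0
    for ln in lengths:
        acc += ln
        if acc >= frac * total:
            return ln
    return 0


def report(output: AssemblyOutput, cfg: PipelineConfig,
           n_input_reads: int | None = None) -> str:
    contigs = [c for c in output.contigs if c.cls == "contig"]
    others = {}
    for c in output.contigs:
        others[c.cls] = others.get(c.cls, 0) + 1
    lens = [len(c.consensus) if c.consensus else c.length for c in contigs]
    lines = ["miniolc assembly report", "======================="]
    if n_input_reads is not None:
        lines.append(f"input reads:      {n_input_reads}")
    lines.append(f"contigs:          {len(contigs)}")
    for cls in ("repeat", "bubble", "unassembled"):
        if others.get(cls):
            lines.append(f"{cls + ':':<18}{others[cls]}")
    lines.append(f"total bases:      {sum(lens)}")
    if lens:
        lines.append(f"longest contig:   {max(lens)}")
        lines.append(f"N50:              {nx_length(lens, 0.5)}")
        lines.append(f"NG50:             {nx_length(lens, 0.5, cfg.genome_size)}")
    m = output.model
    lines.append(f"error model:      median {m.median:.4f}  MAD {m.mad:.4f}  "
                 f"cutoff {m.cutoff:.4f}")
    lines.append(f"overlap records:  {len(output.store)}")
    return "\n".join(lines) + "\n"


def write_outputs(output: AssemblyOutput, outdir: str | Path,
                  cfg: PipelineConfig) -> None:
    from .adjust import write_edits
    from .consensus import write_coverage
    from .simdata import write_fasta

    d = Path(outdir)
    d.mkdir(parents=True, exist_ok=True)
    recs = [(f"{c.name} class={c.cls}", c.consensus or "")
            for c in output.contigs if c.consensus]
    write_fasta(d / "contigs.fasta", recs)
    (d / "assembly.gfa").write_text(output.gfa)
    assemble_mod.write_layout(d / "layout.tsv", output.contigs)
    write_coverage(d / "coverage.tsv",
                   [c for c in output.contigs if c.cls == "contig"])
    write_edits(d / "edits.tsv", output.edits)
    (d / "report.txt").write_text(report(output, cfg))
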