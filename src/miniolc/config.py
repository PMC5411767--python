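"""Pipeline configuration.

One flat dataclass mirrors the assembler's tunable parameters (k-mer size,
sketch sizes, tf-idf weighting, correction depth, trim thresholds, graph
thresholds). Values can be overridden from a YAML file; `defaults_yaml`
prints every key with its default.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

log = logging.getLogger("miniolc")


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


@dataclass
class PipelineConfig:
    # -- global --
    genome_size: int = 100_000       # haploid genome size estimate (bp)
    seed: int = 1                    # master seed for sketching randomness
    threads: int = 1                 # desk scale: sequential fallback is the norm

    # -- k-mer spectrum / tf-idf (first-stage overlap filter) --
    k: int = 16
    # fraction of distinct k-mers recorded as "abundant"; the classic 5e-6
    # default targets corpora with >1e9 distinct k-mers, so at desk-scale
    # corpus sizes we record the top 2% instead (same mechanism, scaled).
    spectrum_cutoff: float = 0.02
    idf_max: int = 3                 # maximum integer idf weight
    idf_a: float = 0.9               # preference exponent in idf formula
    tf_cap: int = 4                  # cap on the tf factor of a weight
    cutoff_interpretation: str = "count"  # "count" | "fraction" (T endpoint)

    # -- sketching --
    sketch_size: int = 512           # weighted-sketch slots for raw reads
    sketch_size_corrected: int = 256  # corrected reads are near-exact; fewer slots suffice
    bottom_size: int = 1500          # bottom-sketch k-mers per read
    min_slot_matches: int = 2        # first-stage acceptance (see methods note)
    weighting: str = "tfidf"         # "tfidf" | "none" | "threshold"
    max_kmer_count: int = 0          # threshold mode: drop k-mers above this count

    # -- overlap --
    min_overlap: int = 500           # bp; shorter overlaps are ignored
    end_slop_bp: int = 100           # dovetail end tolerance: max(100 bp, 3% of len)
    end_slop_frac: float = 0.03

    # -- correction --
    cor_coverage: int = 0            # C; 0 = derive from data / genome_size
    cor_out_coverage: int = 40       # correct the longest reads to this depth
    cor_min_depth: int = 2           # evidence depth for corrected-length support
    cor_min_weight: int = 4          # DAG edge weight below which reads split
    cor_min_piece: int = 500         # bp; discard shorter corrected pieces
    cor_rounds: int = 1
    cor_score: str = "error"         # donation ranking: "error" | "length_identity"

    # -- trimming --
    trim_depth: int = 2              # C: minimum supporting depth
    trim_error: float = 0.045        # E: max overlap error for support
    trim_min_len: int = 500          # L: min supporting overlap / output length
    hairpin_min_partners: int = 5
    hairpin_max_spanning: int = 2
    chimera_max_spanning: int = 1
    span_margin: int = 100           # "spanning" = covers [pos-100, pos+100]

    # -- overlap error adjustment --
    adjust_min_support: float = 0.25  # keep a differing base if >=25% agree with read
    adjust_min_depth: int = 3         # columns below this depth are never edited

    # -- graph construction --
    mad_multiplier: float = 6.0      # cutoff = median + 6 MAD of best-edge errors
    error_floor: float = 0.005       # cutoff floor when MAD degenerates
    window_size: int = 1000          # error-profile window (bp)
    profile_mads: float = 5.0        # placement tolerance: window median + 5 MADs
    repeat_margin_mads: float = 3.0  # "significantly better" margin for repeat checks
    bubble_min_reads: int = 3
    nonmutual_tolerance: int = 500   # bp best-edge length disagreement allowed

    # -- simulated data defaults (study conditions) --
    sim_error_rate: float = 0.10
    sim_coverage: float = 30.0
    sim_length_mu: float = 8.0       # log-normal location (ln bp); e^8 ~ 3 kb
    sim_length_sigma: float = 0.4
    sim_length_min: int = 1000
    sim_length_max: int = 6000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)


def defaults_yaml() -> str:
    return PipelineConfig().to_yaml()
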