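"""Run configuration: a YAML key tree with all defaults pre-filled.

The packaged demo runs with zero edits: when no external input paths are
given, the synthetic generator supplies the data.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field

import yaml

from .screen import CROSS_SPECIES_PARAMS, SearchParams, TriageParams
from .simulate import HGTEvent, LibrarySpec, SimulationConfig


@dataclass
class RunConfig:
    seed: int = 0
    e_value_threshold: float = 1e-10
    min_perfect_match: int = 60
    max_amplicon_len: int = 250
    output_dir: str = "xeno_out"
    # input paths; all optional — empty means "simulate"
    host_fasta: str | None = None
    donor_fasta: str | None = None
    reads_fastq: list[str] = field(default_factory=list)
    host_tree: str | None = None
    donor_tree: str | None = None
    screen: SearchParams = field(default_factory=SearchParams)
    cross_species: SearchParams = field(
        default_factory=lambda: SearchParams(**CROSS_SPECIES_PARAMS)
    )
    triage: TriageParams = field(default_factory=TriageParams)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    ratio_mode: str = "ratio_of_averages"
    loss_policy: str = "strict"

    def __post_init__(self) -> None:
        if self.e_value_threshold <= 0:
            raise ValueError("e_value_threshold must be positive")
        if self.min_perfect_match < 1:
            raise ValueError("min_perfect_match must be >= 1")
        self.screen.e_value_threshold = self.e_value_threshold
        self.cross_species.e_value_threshold = self.e_value_threshold
        self.simulation.seed = self.seed
        for path in [self.host_fasta, self.donor_fasta, self.host_tree,
                     self.donor_tree, *self.reads_fastq]:
            if path and not os.path.exists(path):
                raise FileNotFoundError(f"configured input path not found: {path}")

    # -- (de)serialisation --------------------------------------------------

    def to_yaml(self, path: str) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data, base_dir=os.path.dirname(os.path.abspath(path)))

    @classmethod
    def from_dict(cls, data: dict, base_dir: str = ".") -> "RunConfig":
        data = dict(data)
        for key in ("host_fasta", "donor_fasta", "host_tree", "donor_tree"):
            if data.get(key):
                data[key] = os.path.join(base_dir, data[key]) if not os.path.isabs(
                    data[key]) else data[key]
        if data.get("reads_fastq"):
            data["reads_fastq"] = [
                p if os.path.isabs(p) else os.path.join(base_dir, p)
                for p in data["reads_fastq"]
            ]
        if "screen" in data and isinstance(data["screen"], dict):
            d = data["screen"]
            if "base_freqs" in d:
                d["base_freqs"] = tuple(d["base_freqs"])
            data["screen"] = SearchParams(**d)
        if "cross_species" in data and isinstance(data["cross_species"], dict):
            d = data["cross_species"]
            if "base_freqs" in d:
                d["base_freqs"] = tuple(d["base_freqs"])
            data["cross_species"] = SearchParams(**d)
        if "triage" in data and isinstance(data["triage"], dict):
            data["triage"] = TriageParams(**data["triage"])
        if "simulation" in data and isinstance(data["simulation"], dict):
            sim = dict(data["simulation"])
            if "hgt_events" in sim:
                sim["hgt_events"] = [
                    e if isinstance(e, HGTEvent) else HGTEvent(**e) for e in sim["hgt_events"]
                ]
            if "libraries" in sim:
                sim["libraries"] = [
                    l if isinstance(l, LibrarySpec) else LibrarySpec(**l)
                    for l in sim["libraries"]
                ]
            if "read_len_range" in sim:
                sim["read_len_range"] = tuple(sim["read_len_range"])
            data["simulation"] = SimulationConfig(**sim)
        return cls(**data)
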