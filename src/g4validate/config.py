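"""Run configuration: one structured-text file drives every stage.

Exactly one of ``inputs`` (paths to a structure bundle, trajectory and
restraint table) or ``synthetic`` (a generator spec) must be present.
All thresholds live here with their documented defaults so that every
threshold-sensitive result is auditable; each run writes the resolved
config hash into its summary.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import yaml

from .synthetic import SyntheticSpec

DEFAULT_THRESHOLDS = {
    "noe_tolerance": 1.0,        # Å beyond a bound before a violation is called
    "hbond_distance": 3.0,       # Å donor-acceptor
    "hbond_angle": 135.0,        # deg donor-H-acceptor
    "dihedral_bin": 15.0,        # deg
    "rmsd_window": 1000,         # frames, running average
    "equilibration": 0.1,        # fraction of frames discarded
    "rdf_bin_width": 0.1,        # Å
    "rdf_r_max": 35.0,           # Å
    "bulk_shell_radius": 30.0,   # Å
    "voxel_volume": 0.125,       # Å^3
    "cavity_cutoff": 2.0,        # Å
    "plane_halfwidth": 1.0,      # Å
    "approach_cutoff": 4.5,      # Å
    "coverage": 0.80,            # representative cumulative population
    "n_clusters": 6,
    "cluster_stride": 10,
    "noe_cutoff": 4.5,           # Å, synthetic restraint derivation
    "noe_padding": 0.5,          # Å
}

_THRESHOLD_RANGES = {
    "noe_tolerance": (0.0, 10.0), "hbond_distance": (1.0, 6.0),
    "hbond_angle": (0.0, 180.0), "dihedral_bin": (1.0, 120.0),
    "rmsd_window": (1, 10**7), "equilibration": (0.0, 0.999),
    "rdf_bin_width": (0.001, 5.0), "rdf_r_max": (1.0, 500.0),
    "bulk_shell_radius": (1.0, 500.0), "voxel_volume": (1e-6, 1000.0),
    "cavity_cutoff": (0.1, 20.0), "plane_halfwidth": (0.1, 20.0),
    "approach_cutoff": (0.1, 50.0), "coverage": (1e-9, 1.0),
    "n_clusters": (1, 10**6), "cluster_stride": (1, 10**6),
    "noe_cutoff": (0.5, 50.0), "noe_padding": (0.0, 50.0),
}


@dataclass
class RunConfig:
    seed: int = 0
    temperature: float = 300.0
    output_dir: str = "g4validate-out"
    synthetic: SyntheticSpec | None = None
    inputs: dict | None = None       # bundle, trajectory, restraints, dialect, annotation
    masks: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    manifest: list = field(default_factory=list)  # [{name, replicates, length_us}]

    def __post_init__(self):
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("exactly one of 'synthetic' or 'inputs' must be configured")
        merged = dict(DEFAULT_THRESHOLDS)
        unknown = set(self.thresholds) - set(DEFAULT_THRESHOLDS)
        if unknown:
            raise ValueError(f"unknown thresholds: {sorted(unknown)}")
        merged.update(self.thresholds)
        for key, val in merged.items():
            lo, hi = _THRESHOLD_RANGES[key]
            if not lo <= val <= hi:
                raise ValueError(f"threshold {key}={val} outside [{lo}, {hi}]")
        self.thresholds = merged
        if self.inputs is not None:
            required = {"bundle", "trajectory", "restraints", "restraint_dialect"}
            missing = required - set(self.inputs)
            if missing:
                raise ValueError(f"inputs section missing keys: {sorted(missing)}")

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "temperature": self.temperature,
            "output_dir": self.output_dir,
            "synthetic": None if self.synthetic is None else asdict(self.synthetic),
            "inputs": self.inputs,
            "masks": dict(self.masks),
            "thresholds": dict(self.thresholds),
            "manifest": list(self.manifest),
        }
        if d["synthetic"] is not None:
            d["synthetic"]["ion_schedule"] = [list(x) for x in d["synthetic"]["ion_schedule"]]
        return d

    def hash(self) -> str:
        """Hash of the threshold-sensitive settings (the output location
        does not change results and is excluded)."""
        d = self.to_dict()
        d.pop("output_dir")
        canon = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path_or_stream) -> RunConfig:
    if hasattr(path_or_stream, "read"):
        data = yaml.safe_load(path_or_stream)
    else:
        with open(path_or_stream) as fh:
            data = yaml.safe_load(fh)
    data = data or {}
    synth = data.get("synthetic")
    if synth is not None:
        synth = dict(synth)
        synth["ion_schedule"] = [tuple(x) for x in synth.get("ion_schedule", [])]
        synth = SyntheticSpec(**synth)
    return RunConfig(
        seed=int(data.get("seed", 0)),
        temperature=float(data.get("temperature", 300.0)),
        output_dir=str(data.get("output_dir", "g4validate-out")),
        synthetic=synth,
        inputs=data.get("inputs"),
        masks=data.get("masks") or {},
        thresholds=data.get("thresholds") or {},
        manifest=data.get("manifest") or [],
    )


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
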