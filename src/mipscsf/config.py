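"""Run configuration: documented defaults plus a flat key=value file format."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

from .schedule import InjectionSchedule
from .segmentation import SegmentationConfig

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Top-level run parameters with documented defaults.

    ``baseline_mode`` selects the normalization reference for raw phase
    series: ``pre_injection`` (mean of the t < 0 segment) or
    ``first_block``.
    """

    seed: int = 0
    n_rabbits: int = 8
    polynomial_degree: int = 4
    baseline_mode: str = "pre_injection"
    block_size: int = 300
    out_dir: str = "."
    log_level: str = "INFO"
    # segmentation knobs (flattened into SegmentationConfig)
    n_classes: int = 4
    fuzzifier: float = 2.0
    mrf_beta: float = 0.5
    neighborhood: int = 6
    max_iter: int = 100
    tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.baseline_mode not in ("pre_injection", "first_block"):
            raise ValueError("baseline_mode must be 'pre_injection' or 'first_block'")
        if not 3 <= self.polynomial_degree <= 6:
            raise ValueError("polynomial_degree must be in 3..6")

    @property
    def schedule(self) -> InjectionSchedule:
        return InjectionSchedule.default_protocol()

    @property
    def segmentation(self) -> SegmentationConfig:
        return SegmentationConfig(
            n_classes=self.n_classes,
            fuzzifier=self.fuzzifier,
            mrf_beta=self.mrf_beta,
            neighborhood=self.neighborhood,
            max_iter=self.max_iter,
            tol=self.tol,
            seed=self.seed,
        )


def load_config(path) -> RunConfig:
    """Parse a flat ``key = value`` config file; unknown keys are rejected."""
    known = {f.name: f.type for f in fields(RunConfig)}
    casts = {
        "seed": int, "n_rabbits": int, "polynomial_degree": int, "block_size": int,
        "n_classes": int, "neighborhood": int, "max_iter": int,
        "fuzzifier": float, "mrf_beta": float, "tol": float,
        "baseline_mode": str, "out_dir": str, "log_level": str,
    }
    kwargs = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (s.strip() for s in line.split("=", 1))
        if key not in known:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        kwargs[key] = casts[key](value)
    return RunConfig(**kwargs)
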