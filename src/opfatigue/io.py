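"""File formats and configuration.

RR series travel as one-integer-per-line text files (milliseconds) named
``subj{S}_stage{T}.rr``; tabular artifacts are UTF-8 comma-separated CSV
with a header row; configuration is YAML; derived artifacts (weights,
thresholds, model, report) are JSON.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cohort import ProtocolConfig
from .hrv import RR_MAX_MS, RR_MIN_MS, RRISeries
from .mlp import TrainConfig

__all__ = [
    "read_rri",
    "write_rri",
    "rr_filename",
    "PipelineConfig",
    "load_config",
]

_RR_NAME = re.compile(r"subj(?P<subject>[A-Za-z0-9]+)_stage(?P<stage>\d+)\.rr$")


def rr_filename(subject_id: str, stage: int) -> str:
    sid = subject_id.lstrip("S") or subject_id
    return f"subj{sid}_stage{stage}.rr"


def write_rri(series: RRISeries, path: str | Path) -> Path:
    """Write intervals as one integer (ms) per line."""
    path = Path(path)
    lines = "\n".join(str(int(round(v))) for v in series.intervals)
    path.write_text(lines + "\n")
    return path


def read_rri(path: str | Path) -> RRISeries:
    """Read a ``.rr`` file; subject/stage are parsed from the filename.

    Fails with the offending line number on non-numeric content and
    names the physiological guard when an interval falls outside
    [300, 2000] ms.
    """
    path = Path(path)
    values: list[float] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        try:
            v = float(line)
        except ValueError:
            raise ValueError(f"{path.name}:{lineno}: non-numeric line {line!r}")
        if not RR_MIN_MS <= v <= RR_MAX_MS:
            raise ValueError(
                f"{path.name}:{lineno}: interval {v:g} ms outside the "
                f"physiological guard [{RR_MIN_MS:.0f}, {RR_MAX_MS:.0f}] ms"
            )
        values.append(v)
    if not values:
        raise ValueError(f"{path.name}: empty RR file")
    m = _RR_NAME.search(path.name)
    subject = f"S{m.group('subject')}" if m else ""
    stage = int(m.group("stage")) if m else 0
    return RRISeries(np.array(values), subject_id=subject, stage=stage)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the end-to-end pipeline needs; one seed drives it all."""

    cohort: ProtocolConfig = field(default_factory=ProtocolConfig)
    k: int = 5
    k_range: tuple[int, int] = (2, 10)
    replicates: int = 10
    train: TrainConfig = field(default_factory=TrainConfig)
    folds: int = 5
    seed: int = 0

    def stage_seeds(self) -> dict[str, int]:
        """Deterministic per-stage seeds derived from the global seed."""
        ss = np.random.SeedSequence(self.seed)
        names = ("cohort", "grading", "train", "cv")
        return {
            name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(names, ss.spawn(len(names)))
        }


def load_config(path: str | Path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file.

    Recognised top-level keys: ``seed``, ``cohort`` (ProtocolConfig
    fields), ``grading`` (``k``, ``k_range``, ``replicates``), ``train``
    (TrainConfig fields) and ``folds``.  Unknown keys are rejected.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {"seed", "cohort", "grading", "train", "folds"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    seed = int(raw.get("seed", 0))
    cohort_kwargs = dict(raw.get("cohort", {}))
    grading = dict(raw.get("grading", {}))
    train_kwargs = dict(raw.get("train", {}))
    k_range = tuple(grading.get("k_range", (2, 10)))
    return PipelineConfig(
        cohort=ProtocolConfig(**cohort_kwargs),
        k=int(grading.get("k", 5)),
        k_range=(int(k_range[0]), int(k_range[1])),
        replicates=int(grading.get("replicates", 10)),
        train=TrainConfig(**train_kwargs),
        folds=int(raw.get("folds", 5)),
        seed=seed,
    )
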