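"""Synthetic labelled IBI cohorts with the statistical structure stress induces.

Acute stress shortens the mean inter-beat interval (faster heart rate) and
shrinks its beat-to-beat variability.  The generator reproduces exactly that
structure — per condition a stationary AR(1) process around a condition mean,
plus a per-subject offset applied to both conditions so that generic
(cross-subject) classifiers face realistic inter-subject heterogeneity.

Durations are clipped to the physiologic range, so range filtering is a
no-op on default synthetic data; a contamination fraction can inject
out-of-range beats to exercise the filter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import Condition, IBISequence, PHYSIO_HIGH, PHYSIO_LOW, write_ibi_file


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic multi-subject IBI cohort.

    All durations are in seconds.  ``mu_stressed < mu_nonstressed`` and
    ``sd_stressed < sd_nonstressed`` encode the physiological direction of
    acute stress (shorter, less variable beats).
    """

    n_subjects: int = 15
    beats_per_condition: int = 1000
    mu_nonstressed: float = 0.85
    mu_stressed: float = 0.70
    sd_nonstressed: float = 0.08
    sd_stressed: float = 0.04
    ar_coefficient: float = 0.9
    subject_shift_sd: float = 0.05
    contamination: float = 0.0
    clip_low: float = PHYSIO_LOW
    clip_high: float = PHYSIO_HIGH
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.beats_per_condition < 1:
            raise ValueError("n_subjects and beats_per_condition must be >= 1")
        if not self.mu_stressed < self.mu_nonstressed:
            raise ValueError("mu_stressed must be < mu_nonstressed")
        if self.sd_stressed > self.sd_nonstressed:
            raise ValueError("sd_stressed must not exceed sd_nonstressed")
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        if self.sd_nonstressed < 0 or self.subject_shift_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        if not 0 <= self.contamination < 1:
            raise ValueError("contamination must lie in [0, 1)")
        if not self.clip_low < self.clip_high:
            raise ValueError("clip_low must be < clip_high")


def _ar1(rng: np.random.Generator, n: int, mu: float, sd: float, phi: float) -> np.ndarray:
    """Stationary AR(1) with marginal mean ``mu`` and marginal sd ``sd``."""
    x = np.empty(n)
    innov_sd = sd * np.sqrt(1.0 - phi * phi)
    x[0] = mu + sd * rng.standard_normal()
    eps = innov_sd * rng.standard_normal(n - 1)
    for t in range(1, n):
        x[t] = mu + phi * (x[t - 1] - mu) + eps[t - 1]
    return x


def generate_subject(
    spec: CohortSpec, subject_index: int
) -> tuple[IBISequence, IBISequence]:
    """Generate one subject's (stressed, non-stressed) IBI pair.

    Fully reproducible from ``(spec.seed, subject_index)``: the subject's
    mean offset is drawn once and applied to both conditions; each condition
    is a stationary AR(1) around its shifted mean, clipped to the physiologic
    range.
    """
    if not 0 <= subject_index < spec.n_subjects:
        raise ValueError(f"subject_index {subject_index} out of range")
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), int(subject_index)]))
    offset = spec.subject_shift_sd * rng.standard_normal()

    out = []
    for cond, mu, sd in (
        (Condition.STRESSED, spec.mu_stressed, spec.sd_stressed),
        (Condition.NON_STRESSED, spec.mu_nonstressed, spec.sd_nonstressed),
    ):
        dur = _ar1(rng, spec.beats_per_condition, mu + offset, sd, spec.ar_coefficient)
        dur = np.clip(dur, spec.clip_low, spec.clip_high)
        if spec.contamination > 0:
            n_bad = int(round(spec.contamination * dur.size))
            idx = rng.choice(dur.size, size=n_bad, replace=False)
            # half too short, half too long, clearly outside the range
            lo = rng.uniform(0.5 * spec.clip_low, 0.95 * spec.clip_low, size=n_bad)
            hi = rng.uniform(1.05 * spec.clip_high, 1.5 * spec.clip_high, size=n_bad)
            dur[idx] = np.where(rng.random(n_bad) < 0.5, lo, hi)
        out.append(
            IBISequence(
                subject_id=f"S{subject_index}",
                condition=cond,
                timestamps=np.cumsum(dur),
                durations=dur,
            )
        )
    return out[0], out[1]


def generate_cohort(spec: CohortSpec) -> list[tuple[IBISequence, IBISequence]]:
    """Generate ``spec.n_subjects`` independent (stressed, non-stressed) pairs."""
    return [generate_subject(spec, i) for i in range(spec.n_subjects)]


def write_cohort(spec: CohortSpec, out_dir: str | Path) -> Path:
    """Write per-subject CSV fixtures in the E4 dialect plus a manifest JSON.

    Returns the manifest path.  The manifest records the true generator
    parameters and the file layout.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for i, (stressed, nonstressed) in enumerate(generate_cohort(spec)):
        for seq in (stressed, nonstressed):
            name = f"S{i}_{seq.condition.value}.csv"
            write_ibi_file(seq, out_dir / name)
            files.append(
                {"file": name, "subject_id": seq.subject_id, "condition": seq.condition.value}
            )
    manifest = out_dir / "manifest.json"
    manifest.write_text(
        json.dumps({"spec": spec.__dict__, "files": files}, indent=2, default=float)
    )
    return manifest


def load_cohort(data_dir: str | Path) -> list[tuple[IBISequence, IBISequence]]:
    """Load a cohort written by :func:`write_cohort` back into memory."""
    from .io import read_ibi_file

    data_dir = Path(data_dir)
    manifest = json.loads((data_dir / "manifest.json").read_text())
    by_subject: dict[str, dict[str, IBISequence]] = {}
    for entry in manifest["files"]:
        seq = read_ibi_file(data_dir / entry["file"], entry["subject_id"], entry["condition"])
        by_subject.setdefault(entry["subject_id"], {})[entry["condition"]] = seq
    pairs = []
    for subj in sorted(by_subject, key=lambda s: (len(s), s)):
        conds = by_subject[subj]
        pairs.append((conds[Condition.STRESSED.value], conds[Condition.NON_STRESSED.value]))
    return pairs
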