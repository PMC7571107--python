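#!/usr/bin/env python
"""Optional runner for a locally downloaded WESAD dataset tree.

WESAD (Wearable Stress and Affect Detection; 15 subjects, TSST stress
protocol) is not bundled with this package and is never required by the
test suite.  Given a local tree of the usual layout

    <root>/S2/S2_E4_Data/IBI.csv     Empatica E4 inter-beat intervals
    <root>/S2/S2_quest.csv           protocol timing questionnaire

this script slices each subject's E4 IBI stream into the baseline
(non-stressed) and TSST (stressed) windows using the start/end times in
the questionnaire file, merges the stress segments, and runs the three
evaluation regimes in both image domains.

The questionnaire format varies slightly between WESAD releases; the
parser below expects the usual ``# ORDER``/``# START``/``# END`` rows with
times in minutes.  Verify the condition windows on your copy before
trusting the output.  Results depend on epochs and seeds; the reference
configuration trains 150 epochs for generic models.

Usage:
    python scripts/run_wesad.py --wesad-root /data/WESAD --epochs 150 \
        --domain spatial --out wesad_reports.json
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from ibistress import (
    Condition,
    IBISequence,
    default_test_triples,
    encode_cohort,
    merge_stress_segments,
    read_ibi_file,
    run_regime,
)
from ibistress.classifier import CNNConfig


def parse_quest(path: Path) -> dict[str, tuple[float, float]]:
    """Condition name -> (start, end) in seconds from the quest CSV."""
    order = start = end = None
    for line in path.read_text().splitlines():
        cells = [c.strip() for c in line.split(";")]
        if cells[0] == "# ORDER":
            order = [c for c in cells[1:] if c]
        elif cells[0] == "# START":
            start = [float(c) for c in cells[1:] if c]
        elif cells[0] == "# END":
            end = [float(c) for c in cells[1:] if c]
    if not (order and start and end):
        raise ValueError(f"{path}: could not locate ORDER/START/END rows")
    return {o: (s * 60.0, e * 60.0) for o, s, e in zip(order, start, end)}


def slice_condition(seq: IBISequence, window: tuple[float, float], condition: Condition) -> IBISequence:
    lo, hi = window
    mask = (seq.timestamps >= lo) & (seq.timestamps <= hi)
    return IBISequence(seq.subject_id, condition, seq.timestamps[mask], seq.durations[mask])


def load_subject(root: Path, sid: str, include_amusement: bool) -> tuple[IBISequence, IBISequence]:
    quest = parse_quest(root / sid / f"{sid}_quest.csv")
    seq = read_ibi_file(root / sid / f"{sid}_E4_Data" / "IBI.csv", sid, Condition.NON_STRESSED)

    stress_keys = [k for k in quest if k.lower().startswith("tsst")]
    stressed = merge_stress_segments(
        [slice_condition(seq, quest[k], Condition.STRESSED) for k in stress_keys]
    )
    base_keys = [k for k in quest if k.lower().startswith("base")]
    if include_amusement:
        base_keys += [k for k in quest if k.lower().startswith("fun") or k.lower().startswith("medi")]
    non_parts = [slice_condition(seq, quest[k], Condition.NON_STRESSED) for k in base_keys]
    non = non_parts[0]
    for extra in non_parts[1:]:  # concatenate with recorded joins, like the stress merge
        merged = merge_stress_segments(
            [
                IBISequence(sid, Condition.STRESSED, p.timestamps, p.durations, p.boundaries)
                for p in (non, extra)
            ]
        )
        non = IBISequence(sid, Condition.NON_STRESSED, merged.timestamps, merged.durations, merged.boundaries)
    return stressed, non


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--wesad-root", type=Path, required=True)
    parser.add_argument("--domain", choices=["spatial", "frequency"], default="spatial")
    parser.add_argument("--epochs", type=int, default=150)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--include-amusement", action="store_true",
                        help="Count amusement/meditation as non-stressed (default: baseline only).")
    parser.add_argument("--out", type=Path, default=Path("wesad_reports.json"))
    args = parser.parse_args()

    subject_dirs = sorted(
        (d.name for d in args.wesad_root.iterdir() if d.is_dir() and d.name.startswith("S")),
        key=lambda s: (len(s), s),
    )
    pairs = [load_subject(args.wesad_root, sid, args.include_amusement) for sid in subject_dirs]
    config = CNNConfig(epochs=args.epochs, seed=args.seed)
    reports = []

    for sid in subject_dirs:
        dataset, _ = encode_cohort(pairs, domain=args.domain)
        rep = run_regime(dataset, "person_specific", config, subject=sid, seed=args.seed)
        reports.append(rep.to_row() | {"Subjects": sid})
        print(reports[-1])

    dataset, _ = encode_cohort(pairs, domain=args.domain)
    for triple in default_test_triples(subject_dirs):
        for regime in ("generic", "calibrated_generic"):
            rep = run_regime(dataset, regime, config, test_subjects=list(triple), seed=args.seed)
            reports.append(rep.to_row() | {"Subjects": ",".join(triple)})
            print(reports[-1])

    args.out.write_text(json.dumps(reports, indent=2))
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
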