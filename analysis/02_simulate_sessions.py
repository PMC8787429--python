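#!/usr/bin/env python
"""Generate example synthetic sessions and verify their ground truth.

Writes one acute graded-stimulation session and one chronic singing
session (with audio) under results/sessions/, then re-reads them through
the container to confirm lossless round-tripping.
"""

import argparse
from pathlib import Path

import numpy as np

from pnisig import io, synthdata as sd

OUT = Path(__file__).resolve().parents[1] / "results" / "sessions"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    # acute: graded currents at a reduced trial count for a compact example
    sc = sd.standard_acute_scenario(trials_per_current=8, isi_s=0.1)
    rec, events, gt = sd.gen_acute_session(sc, seed=args.seed)
    io.write_session(OUT / "acute", rec, events=events, extra_meta={"kind": "acute"})
    print(f"acute:   {len(events)} trials, {rec.duration:.1f} s, "
          f"latencies {gt.latencies_ms.min():.2f}-{gt.latencies_ms.max():.2f} ms, "
          f"max evoked amplitude {gt.amplitudes.max():.0f} µV")

    # chronic: one day of singing-related activity
    csc = sd.ChronicScenario(renditions_per_day=30)
    crec, motifs, cgt = sd.gen_chronic_session(csc, day=0, seed=args.seed)
    io.write_session(OUT / "chronic_day0", crec, motifs=motifs, audio=cgt.audio,
                     extra_meta={"kind": "chronic", "day": 0})
    print(f"chronic: {len(motifs)} renditions, {crec.duration:.1f} s, "
          f"{crec.n_channels} channels")

    for name in ("acute", "chronic_day0"):
        back = io.read_session(OUT / name)
        orig = rec if name == "acute" else crec
        assert np.array_equal(back["recording"].samples, orig.samples)
        print(f"round-trip {name}: lossless")


if __name__ == "__main__":
    main()
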