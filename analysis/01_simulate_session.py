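"""Simulate one example control session and export it in every format.

Writes a 2-channel session (pre epoch, 10 x 40-Hz trains, 10 x 20-Hz
trains, post epoch) as native .bin+.json, EDF and events TSV under
scratch/example_session/ (binary formats stay out of results/), and prints
the protocol summary.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from cohort_config import SIM  # noqa: E402

from assrlab import edf  # noqa: E402
from assrlab.lfp_io import write_events, write_layout, write_recording  # noqa: E402
from assrlab.synthetic_data import simulate_session  # noqa: E402

OUT = Path(__file__).resolve().parents[1] / "scratch" / "example_session"


def main() -> None:
    rec, layout = simulate_session(SIM, n_channels=2, animal_id="demo", genotype="control", seed=1)
    OUT.mkdir(parents=True, exist_ok=True)
    write_recording(rec, OUT / "recording.bin", OUT / "recording.json")
    edf.write_edf(rec, OUT / "recording.edf")
    write_events(layout.events, OUT / "events.tsv")
    write_layout(layout, OUT / "layout.json")

    print(f"session: {rec.n_channels} channels, {rec.duration_s:.0f} s at {rec.fs:.0f} Hz")
    for label, start, end in layout.epochs:
        n_ev = sum(start <= ev.onset_s < end for ev in layout.events)
        print(f"  {label:7s} [{start:7.1f}, {end:7.1f}) s  {n_ev} click trains")
    print(f"files written to {OUT}")


if __name__ == "__main__":
    main()
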