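"""Brain-state analysis: spontaneous band power across Pre/ISI/Post epochs.

Builds the five-epoch state-transition table (200-ms bins, 50 per epoch)
for every surviving channel and prints the broadband (30-100 Hz) genotype
contrast per epoch — the readout in which the mutants' quiescent elevation
normalizes during repetitive stimulation.  Tables land in results/state/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from cohort_config import ANALYSIS, STATE_BANDS, make_cohort  # noqa: E402

from assrlab.assr_state import combined_isi_power, isi_epoch_labels  # noqa: E402
from assrlab.cohort import analyze_cohort, per_animal_means  # noqa: E402
from assrlab.stats_report import write_tsv  # noqa: E402

OUT = Path(__file__).resolve().parents[1] / "results" / "state"


def main() -> None:
    _, _, state_table = analyze_cohort(make_cohort(), ANALYSIS, STATE_BANDS)
    OUT.mkdir(parents=True, exist_ok=True)
    write_tsv(state_table, OUT / "state_table.tsv")
    write_tsv(combined_isi_power(state_table, "30-100"), OUT / "combined_isi_30_100.tsv")

    broadband = state_table[state_table["band"] == "30-100"]
    order = ["Pre"] + isi_epoch_labels(state_table) + ["Post"]
    print(f"state table in {OUT}; 30-100 Hz spontaneous power (z^2 per bin):")
    for epoch in order:
        sub = broadband[broadband["epoch"] == epoch]
        g = per_animal_means(sub, "mean_power").groupby("genotype")["mean_power"].mean()
        ratio = g["mutant"] / g["control"]
        print(
            f"  {epoch:6s} control {g['control']:.4f}  mutant {g['mutant']:.4f}  "
            f"mutant/control {ratio:.2f}"
        )


if __name__ == "__main__":
    main()
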