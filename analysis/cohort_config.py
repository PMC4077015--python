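"""Shared cohort definition for the numbered analysis drivers.

A scaled-down version of the study cohort (3 control + 3 mutant animals,
4 channels each, 10 click trains per session instead of 7 + 6 animals x 6
tetrodes x 50 trains) keeps every driver under a minute while preserving
the qualitative genotype contrast.  All drivers share one seed so their
tables describe the same simulated experiment.
"""

from assrlab.lfp_io import AnalysisConfig
from assrlab.synthetic_data import SimulationConfig

SEED = 2026
N_CONTROL, N_MUTANT, N_CHANNELS = 3, 3, 4
SIM = SimulationConfig(n_trials=10)
ANALYSIS = AnalysisConfig()
STATE_BANDS = {
    "21-30": (21.0, 30.0),
    "35-44": (35.0, 44.0),
    "71-80": (71.0, 80.0),
    "30-100": (30.0, 100.0),
}


def make_cohort():
    from assrlab.synthetic_data import make_genotype_cohort

    return make_genotype_cohort(N_CONTROL, N_MUTANT, N_CHANNELS, SIM, seed=SEED)
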