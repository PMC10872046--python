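"""Shared configuration for the numbered analysis scripts.

Every script reads/writes under ``results/analysis`` and derives its
randomness from one master seed, so the whole sequence is reproducible by
running the scripts in order.
"""

from pathlib import Path

RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"
MASTER_SEED = 20260920

PERIODS = {"T1": (1992, 1996), "T2": (2013, 2017)}
N_SPECIES = 200
N_ZONES = 5
N_REPLICATES = 5
TAU_MAIN = 0.9
BOOTSTRAP_B = 1000
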