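"""Shared paths and seeding for the numbered analysis drivers."""

from pathlib import Path

import numpy as np

ROOT = Path(__file__).resolve().parents[1]
RESULTS_DIR = ROOT / "results"
#: Raw simulated inputs are bulky and fully regenerable from the seed, so
#: they live under scratch/; only summary tables go to results/.
DATA_DIR = ROOT / "scratch" / "data"

#: Master seed of the analysis run; every driver derives child seeds.
SEED = 20110913


def spawn_seeds(seed: int, n: int) -> list[int]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]
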