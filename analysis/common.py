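"""Shared paths and settings for the numbered analysis scripts.

Run the scripts from the repository root in order (01, 02, ...); small
result tables land under results/, bulky intermediates (SAM files,
figures) under scratch/.
"""

from pathlib import Path

RESULTS = Path("results")
SCRATCH = Path("scratch")

READS_DIR = SCRATCH / "reads"
FIG_DIR = SCRATCH / "figures"

SEED = 20210

# read-level simulation: 4 libraries, realistic isomiR/NTA rates
N_SAMPLES = 4
N_READS = 20_000
ISOMIR_SD = 1.0
NTA_PROB = 0.1

# demo libraries are far below a production 500k-read cutoff; QC uses a
# threshold matched to the simulated depth
MIN_READS = 1000


def outdir(name: str) -> Path:
    p = RESULTS / name
    p.mkdir(parents=True, exist_ok=True)
    return p
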