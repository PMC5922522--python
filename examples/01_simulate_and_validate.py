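"""Simulate a small genome with planted deletions and validate the truth set.

Runs the full workflow: per-base depth extraction, permutation + chi-square
tests against a whole-chromosome background, flank (concavity) tests, and
breakpoint seeking with evidence classification.
"""

from pathlib import Path
import tempfile

import cnvlossverify as cv
from cnvlossverify.depth_tests import DepthTestConfig

with tempfile.TemporaryDirectory() as td:
    spec = cv.SimulationSpec(ref_length=150_000, n_deletions=6, seed=42)
    paths = cv.simulate_dataset(spec, Path(td))

    report = cv.run_full_validation(
        paths["bam"], paths["fasta"], str(paths["truth_bed"]),
        DepthTestConfig(n_resamples=999, seed=1),
    )
    cols = ["chrom", "start", "end", "mean_depth", "perm_p", "chi2_p", "evidence"]
    print(report.table[cols].to_string(index=False))
    print()
    print("permutation rejections:", report.summary["permutation_whole"])
    print("evidence classes:      ", report.summary["evidence_proportions"])

print(
    "\nEach row is one candidate loss: a small permutation p (floor 1/1000)"
    "\nmeans the region's read depth is significantly below background —"
    "\nexpected for every planted deletion; 'break_read' marks candidates"
    "\nwhose exact junction was recovered from assembled reads."
)
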