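"""Recover exact deletion breakpoints by assembly and split alignment.

Plants homozygous deletions, simulates 10x error-free paired reads, then
assembles the reads near each candidate into contigs and split-aligns them
to the local reference: a contig decomposing into a prefix ending at L and
a suffix resuming at R is direct break-read evidence for deleting [L, R).
"""

from pathlib import Path
import tempfile

import cnvlossverify as cv
from cnvlossverify.synthetic_data import make_reference, plant_deletions, simulate_alignments

spec = cv.SimulationSpec(
    ref_length=200_000, n_deletions=8, deletion_length_range=(300, 4000),
    hom_fraction=1.0, mean_depth=10.0, error_rate=0.0, seed=3,
)
with tempfile.TemporaryDirectory() as td:
    out = Path(td)
    ref = make_reference(spec, out / "ref.fa")
    haps, truth = plant_deletions(ref, spec)
    bam = simulate_alignments(haps, truth, out / "reads.bam")

    calls, summary = cv.seek_breakpoints(
        bam, out / "ref.fa", [d.interval for d in truth.deletions],
        cv.BreakpointConfig(k=21),
    )

print(f"{'planted':>22}  {'called':>22}  evidence    support  exact")
for d, c in zip(truth.deletions, calls):
    planted = f"{d.interval.start}-{d.interval.end}"
    called = f"{c.left_break}-{c.right_break}"
    exact = (c.left_break, c.right_break) == (d.interval.start, d.interval.end)
    print(f"{planted:>22}  {called:>22}  {c.evidence:<10}  {c.support_count:>7}  {exact}")
print(f"\nevidence proportions: {summary}")
print(
    "\n'support' counts reads carrying the junction-spanning sequence;"
    "\nexact=True means the called breakpoints equal the planted ones"
    "\n(junctions are left-normalized through chance microhomology)."
)
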