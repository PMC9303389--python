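"""First-passage model of removal by backtracking.

The enzyme ratchets the stalled polymerase one base pair upstream; the
un-ratcheted motor then diffuses until the whole RNA has threaded back and
the polymerase falls off near the promoter.  This script compares mean
removal times across stall-site distances, against the exact Markov-chain
hitting times, and shows the RNA-shortening and oligo-block limits.
"""

from stallkin import (
    WalkParams,
    exact_mean_first_passage,
    mean_removal_time_vs_distance,
)

template = WalkParams(stall_position=20, step_rate=0.05, bias=0.5, absorb_at=1)
df = mean_removal_time_vs_distance(template, [20, 36, 83], n=400, seed=1)
print("stall distance (bp)   MC mean (s)   SE (s)   exact (s)")
for row in df.itertuples(index=False):
    exact = exact_mean_first_passage(
        WalkParams(stall_position=int(row.distance), step_rate=0.05, bias=0.5,
                   absorb_at=1)
    )
    print(
        f"{row.distance:19d}   {row.mean_s:11.0f}   {row.se_s:6.0f}   {exact:9.0f}"
    )
print(f"superlinear growth with distance: {df.attrs['superlinear']}")

short_rna = WalkParams(stall_position=83, step_rate=0.05, bias=0.5, absorb_at=82)
print(
    f"\nRNA degraded (absorb one step upstream): mean "
    f"{exact_mean_first_passage(short_rna):.0f} s regardless of distance"
)
blocked = WalkParams(stall_position=20, step_rate=0.05, bias=0.05, absorb_at=1)
print(
    f"upstream threading blocked (bias 0.05): mean "
    f"{exact_mean_first_passage(blocked):.3g} s"
)

print(
    "\nUnbiased diffusion makes the mean removal time grow roughly with the"
    "\nsquare of the backtracking distance - the superlinearity seen in the"
    "\nstall-site series - while degrading the RNA collapses it and blocking"
    "\nupstream threading lengthens it enormously."
)
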