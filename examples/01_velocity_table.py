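"""Rank competing electron-transfer pathways by abundance-weighted velocity.

A radical hole hopping between redox-active residues can usually reach the
same acceptor through several donors.  The raw tunneling rate (distance
ruler + Marcus barrier) is not the right figure of merit, because a donor
only transfers when it is in its reactive (deprotonated) form.  Weighting
each rate by the reactive-form abundance gives a transfer *velocity*, and
ranking by velocity can reorder the pathways dramatically: a close, fast
couple with a scarce reactive form can lose to a slower but always-ready
one.

This script builds the packaged nine-couple benchmark table and prints the
full velocity report, flagging the winning donor for each radical acceptor.
"""

from etpath import rank_pathways, table_fixture

couples, abundances = table_fixture()
records = rank_pathways(couples, abundances)

header = f"{'donor':>8} {'acceptor':>11} {'R/A':>5} {'log k':>6} {'abund':>9} {'log v':>6}  top"
print(header)
print("-" * len(header))
for r in records:
    print(
        f"{r.donor_label:>8} {r.acceptor_label:>11} {r.distance_mean:>5.1f} "
        f"{r.log10_rate:>6.1f} {r.abundance:>9.1e} {r.log10_velocity:>6.1f}"
        f"  {'*' if r.top_for_acceptor else ''}"
    )

print()
for r in records:
    if r.top_for_acceptor:
        print(
            f"fastest route to {r.acceptor_label}: {r.donor_label} "
            f"(log v = {r.log10_velocity:.1f})"
        )
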