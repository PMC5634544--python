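"""Continuous wakefulness: find the daily limit cycle of biological debt.

Builds the standard scenario with no sleep (TST = 0, equal energy rates
toward waking effort and investment), locates the fixed points of the
start-of-day-debt Poincaré map, and prints the stable cycle.  The stable
fixed point is the debt level an always-awake organism settles into; its
time average over the day is the baseline that every sleep strategy must
hold to make energy comparisons fair.
"""

import sleepenergy as se

params = se.ModelParameters(TST_h=0.0)  # p_W=1.3, p_B1=0.7, m_C=5, A=2.5
print("scenario:", params.to_dict())

for cyc in se.find_fixed_points(params):
    print(
        f"fixed point BD0 = {cyc.BD0:.5f}  ({cyc.stability}), "
        f"mean debt over the cycle m_BD = {cyc.m_BD:.5f}"
    )

wake = se.solve_strategy_wake(params.with_(TST_h=8.0))
print(f"\nWake baseline: m_BD = {wake.m_BD:.5f}, mean MR m_MR1 = {wake.m_MR:.3f}")
print("(the unstable fixed point bounds the basin: debt started above it diverges)")
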