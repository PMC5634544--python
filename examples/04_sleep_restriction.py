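"""Multi-day sleep restriction and the escape from homeostasis.

Takes the rates resolved for an 8 h, MAI-0.4, rho-0.3 strategy, then holds
them fixed while shrinking the sleep quota.  Mild restriction settles at an
elevated but stable daily debt; below ~4 h no steady state is reached, and
near-total restriction escalates — investment can no longer service the
requirements accumulated during long wake.
"""

import sleepenergy as se

params = se.ModelParameters()
wake = se.solve_strategy_wake(params)
mp = se.match_mean_BD(wake.m_BD, 0.3, 0.4, params)
rates = (mp.r_Ww, mp.r_Bw, mp.r_Ws, mp.r_Bs)
print("fixed rates (r_Ww, r_Bw, r_Ws, r_Bs):", tuple(round(r, 4) for r in rates))

for tst in (8.0, 6.0, 3.0, 1.0):
    p = params.with_(TST_h=tst).with_rates(*rates)
    run = se.multiday_run(12, p, BD_init=mp.cycle.BD0)
    means = run.days["mean_BD"]
    print(
        f"TST={tst:4.1f} h: day-1 mean BD {means.iloc[0]:.3f} -> day-12 "
        f"{means.iloc[-1]:.3f}  steady={run.steady_state}  "
        f"escalating={run.escalation}"
    )
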