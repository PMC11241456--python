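"""Solve the zero-loss penalty fee for one clinic day.

A day books nt = 20 patients at fee Pf = 100 with material cost cm = 20 per
patient seen and personnel cost cp = 1100; only ns = 10 show up.  With a
classifier show-up rate beta = 0.5, the 10 vacated slots are expected to
yield 2.5 penalty-paying reappointments and 2.5 standard-fee newcomers.  The
penalty fee phi is solved so the revised revenue is exactly zero.
"""

from noshowpricing import (
    PricingParams,
    expected_revenue,
    penalty_cost,
    penalty_rate,
    pricing_report,
    revised_revenue,
    slot_fill,
)

params = PricingParams(pf=100, cm=20, cp=1100, nt=20, ns=10, beta=0.5)

fill = slot_fill(params.nn, params.beta)
print(f"no-shows nn = {params.nn:.0f}")
print(f"expected reappointments nnr = {fill.nnr:.2f} (pay the penalty fee)")
print(f"expected new patients  nsn = {fill.nsn:.2f} (pay the standard fee)")
print(f"expected full-attendance revenue Er = {expected_revenue(params):.2f}")

phi = penalty_cost(params)
print(f"\nzero-loss penalty fee phi = {phi:.2f}")
print(f"penalty rate = {penalty_rate(phi, params.pf):.1f}% of the standard fee")
print(f"plug-back check: revised revenue at phi = {revised_revenue(params, phi):.2e}")

report = pricing_report(params)
print(f"subsidy regime (phi < cm): {report.below_material_cost}")
print(f"super-fee regime (phi > Pf): {report.above_full_fee}")
print("\nphi = 60 here: each of the 2.5 expected reappointments must pay 60")
print("(40 above material cost) to close the day's 100-unit shortfall.")
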