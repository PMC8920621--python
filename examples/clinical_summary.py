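"""PASI-based efficacy summary of a two-arm psoriasis trial.

Takes arm-level summary inputs (PASI means before/after treatment,
efficacy category counts, post-treatment itching summaries), computes the
PASI reduction measures, total effective rates, and the two group
comparison tests, and prints them the way a trial report would.
"""

from dermamesh import (
    GroupOutcome,
    PasiPair,
    chi_square_2xk,
    delta_pasi,
    delta_pasi_percent,
    round_half_up,
    total_effective_rate,
    welch_t_from_summary,
)

# observation arm = oral decoction + medicated bath; control = oral only
observation_pasi = PasiPair(before=28.25, after=5.61)
observation = GroupOutcome(cured=71, markedly_effective=213, effective=32, ineffective=40)
control = GroupOutcome(cured=32, markedly_effective=158, effective=63, ineffective=103)

print(f"observation dPASI  = {round_half_up(delta_pasi(observation_pasi))} points")
print(f"observation dPASI% = {round_half_up(delta_pasi_percent(observation_pasi))}%")
print(f"total effective rate: observation {round_half_up(total_effective_rate(observation))}%"
      f" vs control {round_half_up(total_effective_rate(control))}%")

chi = chi_square_2xk([
    [observation.n - observation.ineffective, observation.ineffective],
    [control.n - control.ineffective, control.ineffective],
])
print(f"effective vs ineffective chi2 = {chi.statistic:.2f} (df={chi.df}), p = {chi.pvalue:.2e}")

itch = welch_t_from_summary(3.03, 1.01, 356, 3.71, 1.06, 356)
print(f"post-treatment itching Welch t = {itch.statistic:.2f} (df={itch.df:.0f}), p = {itch.pvalue:.2e}")

# dPASI is the absolute PASI reduction; dPASI% the relative reduction that
# drives the four efficacy categories (cut-offs 90/60/30%).  The chi-square
# compares arms on effective vs ineffective; the Welch t compares the
# 0/2/4/6 itching scores after treatment.
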