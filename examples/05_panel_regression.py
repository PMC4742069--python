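"""Which regulators track Slc25a25 protein abundance?

A per-mouse panel measures Slc25a25 protein (densitometry) and eight
candidate regulator transcripts (qPCR).  Backward elimination fits a
pooled multiple regression over the NoEx/0h/1h groups and repeatedly drops
the least significant predictor; per-group Pearson correlations give the
simple-association view.
"""

from riboshift import PanelConfig, group_correlations, panel_regression, simulate_panel

# the generator plants Pmpca +2.81, Immp2l -3.32, Nrf2 -0.59, Mmp2 +0.275
panel = simulate_panel(PanelConfig(seed=8))
print(panel.head(3).round(2).to_string(index=False))

trace = panel_regression(panel)
print("\nremoved (least significant first):", trace.removed)
final = trace.final
print("final model (n = {}, R^2 = {:.3f}):".format(final.n, final.r_squared))
print(final.summary_frame().round(4))
# Inert predictors leave the model first; the retained coefficients
# approximate the planted effects: positive Pmpca (protein maturation),
# negative Immp2l and Nrf2 (degradation-linked), small positive Mmp2.

edges = group_correlations(panel)
strongest = edges.loc[edges["r"].abs().sort_values(ascending=False).index[:3]]
print("\nstrongest per-group correlations with Slc25a25 protein:")
print(strongest.round(3).to_string(index=False))
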