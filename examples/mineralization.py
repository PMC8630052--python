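"""Detect ¹³CO₂ mineralization onset in a headspace time series.

Simulates a noiseless series shaped like a fast-responding soil microcosm
(24-h lag, saturating rise) and computes the atom% excess over background,
flagging the first time point exceeding 3× the measurement SD.
"""

from sipquant import mineralization_excess, simulate_mineralization

series = simulate_mineralization(
    k_rate=0.03, lag_h=24.0, amplitude=4.5, background=1.1, sd=0.0
)
df = mineralization_excess(series, background_atom_percent=1.1, measurement_sd=0.05)
print(df.to_string(index=False))
onset = df.loc[df["detected"], "time_h"]
print(f"mineralization detected from t = {onset.iloc[0]:.0f} h")
print(f"final excess: {df['excess'].iloc[-1]:.2f} atom% above the 1.1 atom% background")
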