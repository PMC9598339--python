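"""Recompute discriminant metrics from published-style confusion tables
and convert calibration errors between mmol/L and mg/dL.
"""

from uraman import ConfusionMatrix, classification_metrics, convert_concentration

tables = {
    "LDA, assayed concentrations (per sample)": ConfusionMatrix(13, 7, 9, 11),
    "LDA, PLS-predicted concentrations (per spectrum)": ConfusionMatrix(85, 28, 42, 77),
    "PLS-DA, full spectra (per spectrum)": ConfusionMatrix(92, 21, 22, 97),
}
for name, cm in tables.items():
    pct = classification_metrics(cm).as_percent()
    print(f"{name}: accuracy {pct['accuracy']}%, "
          f"sensitivity {pct['sensitivity']}%, specificity {pct['specificity']}%")

print()
creat = convert_concentration(3.6, "creatinine", "mmolL_to_mgdL")
gluc = convert_concentration(5.1, "glucose", "mmolL_to_mgdL")
print(f"creatinine RMSEcv 3.6 mmol/L = {creat:.1f} mg/dL (rounds to {round(creat)})")
print(f"glucose    RMSEcv 5.1 mmol/L = {gluc:.1f} mg/dL (rounds to {round(gluc)})")

# Sensitivity counts correct DMHBP calls, specificity correct controls;
# the mg/dL values follow from the molar masses (creatinine 113.12,
# glucose 180.16 g/mol) via mg/dL = mmol/L x M / 10.
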