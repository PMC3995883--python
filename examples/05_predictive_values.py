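"""Base-rate-adjusted predictive values for screening decisions.

Sensitivity and specificity belong to the test; what a positive screen
means for a patient depends on the prevalence of the condition in the
population being screened.
"""

from normscreen import predictive, pv_grid, sample_prevalence

# Published operating points of the delayed-recall screen
rows = [("AD@10.5", 0.980, 0.938), ("MCI@15.5", 0.899, 0.799)]
grid = pv_grid(rows, [0.03, 0.10, 0.20, 0.30, 0.50])
print(grid.to_string(index=False))

pv = predictive(0.899, 0.799, 0.03)
print(f"\nAt a 3% community prevalence the MCI screen's PPV is only "
      f"{pv.ppv:.1%}, while its NPV is {pv.npv:.1%}:")
print("a negative result confidently rules out impairment, but a positive")
print("one mostly selects false alarms - the test belongs in high-risk")
print("memory-clinic populations, not general screening.")

print(f"\nObserved clinic prevalences: MCI {sample_prevalence(134, 631)}%, "
      f"AD {sample_prevalence(97, 631)}% of 631 screened.")
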