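"""Individual-level quality control on an accelerometer metadata table.

An individual is excluded when any QC flag is set, or when the recording
error count exceeds Q3 + 1.5*IQR across the cohort.
"""

from actisleep import IndividualMeta, qc_exclude

meta = [
    IndividualMeta("ukb_0001", n_errors=0),
    IndividualMeta("ukb_0002", n_errors=0),
    IndividualMeta("ukb_0003", n_errors=1),
    IndividualMeta("ukb_0004", n_errors=1),
    IndividualMeta("ukb_0005", n_errors=100),
    IndividualMeta("ukb_0006", n_errors=0, poor_wear_time=True),
]

result = qc_exclude(meta)
print(f"error-count threshold Q3 + 1.5*IQR = {result.error_threshold:.2f}")
print(f"kept ({len(result.kept)}): {', '.join(result.kept)}")
for iid, reasons in result.excluded.items():
    print(f"excluded {iid}: {', '.join(reasons)}")
print()
print("ukb_0005 is an error-count outlier; ukb_0006 fails the wear-time flag.")
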