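"""Quantify PSI from rMATS-dialect tables and apply the study filters.

Run examples/01_simulate_dataset.py first (it writes example_output/simulated).
"""

from pathlib import Path

from asinherit import filter_events, group_mean_psi, psi_table, read_rmats_table, read_sample_sheet

data = Path("example_output/simulated")
sheet = read_sample_sheet(data / "sample_sheet.tsv")
groups = dict(line.split("\t") for line in (data / "groups.tsv").read_text().splitlines()[1:])
g1, g2 = groups["SAMPLE_1"].split(","), groups["SAMPLE_2"].split(",")

events, counts = read_rmats_table(data / "SE.MATS.JC.txt", "SE", g1, g2)
print(f"{len(events)} SE events, {len(counts)} (event, sample) count records")

# keep events with mean total junction count >= 10 in every (strain, sex) cell
# and located on autosomes
rep_groups = {
    f"{strain}_{sex}": grp["sample_id"].tolist()
    for (strain, sex), grp in sheet.groupby(["strain", "sex"])
}
report = filter_events(events, counts, rep_groups)
print(
    f"filters: {report.n_input_events} in -> {report.n_after_lowcount} after "
    f"low-count -> {report.n_after_autosome} after autosome"
)

kept = counts[counts["event_id"].isin(set(report.kept_events))]
psi = psi_table(kept)  # length-normalised PSI, NaN where coverage is zero
gpsi = group_mean_psi(psi, sheet)
print("\nper-(strain, sex) mean PSI of the first surviving event:")
first = gpsi[gpsi["event_id"] == report.kept_events[0]]
print(first[["strain", "sex", "mean_psi", "n_replicates"]].to_string(index=False))
print(
    "\nmean_psi is the replicate average each comparison group contributes to "
    "the inheritance classification."
)
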