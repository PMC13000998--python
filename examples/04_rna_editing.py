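"""Call RNA-editing sites from a simulated read-count pileup.

Plants three C-to-U edits of known efficiency in a small CDS, simulates a
pileup at ~80x coverage with a 0.5% error floor, and applies the standard
thresholds (coverage >= 10, >= 3 edited reads, >= 10% edited fraction).
The passed sites recover the planted positions; efficiency is the edited
read fraction.
"""

from morffokit.editing import annotate_effect, classify_sites, sites_to_frame, summarize_editing
from morffokit.io_formats import SequenceRecord
from morffokit.seqsim import simulate_pileup

cds = SequenceRecord("psbA_like", "ATG" + "TCA" * 80)
planted = [(5, 0.9), (32, 0.4), (80, 0.15)]
pileup, truth = simulate_pileup(cds, planted, coverage_mean=80, error_rate=0.005, seed=3)

sites = [annotate_effect(s, cds, s.pos) for s in classify_sites(pileup)]
passed = [s for s in sites if s.passed]
print(sites_to_frame(passed).to_string(index=False))

summary = summarize_editing(sites, {cds.id: len(cds.seq)})
print(f"\nplanted: {planted}")
print(f"passed sites: {summary['sites_passed']}; site frequency {summary['overall_site_frequency']:.4f}")
print("codon_pos and the amino-acid columns show each edit's coding effect (silent when ref_aa == edit_aa).")
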