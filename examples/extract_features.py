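"""Per-cycle time/frequency features and what separates the classes.

Featurizes one record of each class and prints the feature means that
carry the diagnostic signal: the S2/cycle intensity ratio (pulmonary
hypertension loudens S2) and the S2 peak-pair phase difference (the
A2-P2 split widens).
"""

from pcgpah.fusion_classify import featurize_cycles
from pcgpah.synthetic_pcg import generate_record, spec_for_class

print(f"{'class':10s} {'cycles':>6s} {'i_ratio':>8s} {'pos_s2 (ms)':>12s}")
for label in ("Normal", "CHD", "CHD-PAH"):
    rec, _ = generate_record(spec_for_class(label, seed=3))
    rec = rec.normalized()
    table, _ = featurize_cycles(rec)
    print(
        f"{label:10s} {len(table):6d} "
        f"{table['i_ratio'].mean():8.3f} "
        f"{1000 * table['pos_s2'].mean():12.1f}"
    )
# i_ratio rises monotonically Normal -> CHD -> CHD-PAH (S2 gains energy
# relative to the whole cycle); pos_s2 approaches the simulated 40 ms
# A2-P2 split for the CHD-PAH class.
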