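"""Conserved vs strain-specific clusters and the RC statistic.

Compares the two packaged reference inventories twice: with the given
(published, homology-based) conservation map, and with the map inferred
from domain architecture alone.  RC = 2*Cab/(A+B)*100 is the Dice-type
percentage of the two repertoires that is conserved.
"""

from bgcrep import compute_rc, infer_conservation, load_fixture
from bgcrep.repertoire import load_fixture_map

tp = load_fixture("TP-A0598")
nbrc = load_fixture("NBRC3934")

for label, cmap in [
    ("given map", load_fixture_map()),
    ("inferred from architecture", infer_conservation(tp, nbrc)),
]:
    res = compute_rc(tp, nbrc, cmap)
    print(f"\n{label}: A={res.a_count} B={res.b_count} Cab={res.cab}")
    print(f"  RC = {res.rc}% ({float(res.rc_exact):.2f}% exact)")
    print(f"  {res.strain_a}: {res.frac_shared_a}% shared / {res.frac_specific_a}% specific")
    print(f"  {res.strain_b}: {res.frac_shared_b}% shared / {res.frac_specific_b}% specific")
    print(f"  conserved: {', '.join(res.shared_a)}")
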