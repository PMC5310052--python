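"""Physical bin assignment of markers across nested translocation lines.

Five lines each retain a distal segment of the alien arm, nested from
smallest to largest.  A marker present in lines i..n but absent before
maps between breakpoints i-1 and i.
"""

import pandas as pd

from intronit import assign_bins
from intronit.epcr import LinePanel

lines = ["NAU421", "NAU428", "NAU429", "NAU433", "NAU435"]
presence = pd.DataFrame(
    {"NAU421": [1, 0, 0, 0], "NAU428": [1, 1, 0, 0], "NAU429": [1, 1, 1, 0],
     "NAU433": [1, 1, 1, 0], "NAU435": [1, 1, 1, 1]},
    index=["m_tip", "m_mid", "m_deep", "m_prox"])

panel = LinePanel(lines, presence)
for marker_id, a in assign_bins(panel).items():
    where = (f"between {a.largest_nonretaining} and {a.smallest_retaining}"
             if a.largest_nonretaining and a.smallest_retaining
             else "distal of every breakpoint" if a.bin_index == 0
             else "proximal of every breakpoint")
    print(f"{marker_id}: bin {a.bin_index} ({where}), "
          f"consistent={a.consistent}")
# Markers present in every line sit distal-most (bin 0); each additional
# absence pushes the marker one breakpoint proximally.
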