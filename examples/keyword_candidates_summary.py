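"""Keyword-based candidate selection and the summary table.

Builds a synthetic annotation table, selects candidates per functional
class, fabricates screening decisions for them, and renders the
per-species summary with subtotals and the combined total.
"""

import pandas as pd

from magscreen import (
    MagDecision,
    MagStatus,
    Rule,
    keyword_candidates,
    render_table,
    summarize,
)

rows = (
    [(f"ets{i}", "NADH dehydrogenase subunit") for i in range(6)]
    + [(f"na{i}", "sodium/proton antiporter") for i in range(4)]
    + [(f"abc{i}", "ABC transporter permease") for i in range(8)]
    + [(f"ch{i}", "outer membrane porin") for i in range(3)]
    + [(f"hyp{i}", "hypothetical protein") for i in range(20)]
)
annotations = pd.DataFrame(rows, columns=["id", "product"])

by_class = keyword_candidates(annotations)
classes = {gid: cls for cls, ids in by_class.items() for gid in ids}
print("candidates per class:",
      {cls.value: len(ids) for cls, ids in by_class.items()})

# pretend the phylogenetic screen accepted every third candidate
decisions = []
for i, gid in enumerate(sorted(classes)):
    if i % 3 == 0:
        decisions.append(MagDecision(gid, MagStatus.FINAL_MAG,
                                     Rule.HYPEROSMOTIC_CLADE))
    else:
        decisions.append(MagDecision(gid, MagStatus.REJECTED,
                                     Rule.NONHYPEROSMOTIC))

summary = summarize(decisions, classes=classes, gains=["ets0", "gainX"],
                    losses=["lost_mscl"], species="demo species")
print(render_table(summary))

# Subtotals are row sums of the four class columns; the total combines
# final functional MAGs with comparative-genomics gains and losses,
# subtracting genes found by both routes.
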