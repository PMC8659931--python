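"""Per-class metrics from a 3-class confusion matrix.

Rows are true classes, columns predictions, in the fixed order (resting,
picking, coordination).  PPV (precision), TPR (recall), FNR and FDR are
computed per class, plus total accuracy; percentages can be printed with
banker's rounding or truncation, since published tables mix both.
"""

import numpy as np

from levelk_eeg import ConfusionMatrix, class_metrics, first_order_errors_only
from levelk_eeg.metrics import format_percent

cm = ConfusionMatrix(np.array([
    [589, 11, 0],
    [3, 89, 28],
    [0, 28, 92],
]))
stats = class_metrics(cm)
print(f"total accuracy: {format_percent(stats['accuracy'], mode='truncate')}% "
      f"({stats['n_correct']}/{stats['total']})")
for label, vals in stats["per_class"].items():
    print(f"  {label:>12}: PPV {format_percent(vals['ppv'])}%  "
          f"TPR {format_percent(vals['tpr'])}%  "
          f"FNR {format_percent(vals['fnr'])}%  FDR {format_percent(vals['fdr'])}%")
print(f"errors only between adjacent reasoning depths: {first_order_errors_only(cm)}")
# resting is never confused with coordination in either direction: the two
# non-adjacent depths are perfectly separated, errors involve picking only.
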