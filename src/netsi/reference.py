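"""Published worked example used to validate the reporting arithmetic.

Sixteen (network, condition) regression summaries for the contrast-sensitivity
term — T-score, two-sided p-value and step-up-FDR-adjusted p-value as printed
at 4-decimal precision — serve as fixed inputs for checking the T -> p mapping
and the FDR adjustment. They are data, not computed quantities.
"""

from __future__ import annotations

from typing import NamedTuple

__all__ = ["CSTest", "CS_TERM_TESTS", "SIGNIFICANT_ENTRIES"]


class CSTest(NamedTuple):
    network: str
    condition: str
    t_score: float
    p_value: float
    p_fdr: float


CS_TERM_TESTS: tuple[CSTest, ...] = (
    CSTest("VN", "rest", -0.4105, 0.6815, 0.9805),
    CSTest("VN", "task", 2.9911, 0.0028, 0.0148),
    CSTest("DMN", "rest", 0.0688, 0.9452, 0.9805),
    CSTest("DMN", "task", 3.1532, 0.0016, 0.0129),
    CSTest("SMN", "rest", 3.3426, 0.0008, 0.0129),
    CSTest("SMN", "task", -0.0999, 0.9204, 0.9805),
    CSTest("BGN", "rest", 0.0325, 0.9741, 0.9805),
    CSTest("BGN", "task", -0.1133, 0.9098, 0.9805),
    CSTest("CEN", "rest", -0.0675, 0.9462, 0.9805),
    CSTest("CEN", "task", -0.2595, 0.7953, 0.9805),
    CSTest("DAN", "rest", 1.0753, 0.2823, 0.7721),
    CSTest("DAN", "task", 1.5118, 0.1306, 0.5224),
    CSTest("FTN", "rest", -0.1088, 0.9134, 0.9805),
    CSTest("FTN", "task", -0.7326, 0.4638, 0.9805),
    CSTest("SN", "rest", 1.0592, 0.2895, 0.7721),
    CSTest("SN", "task", 0.0245, 0.9805, 0.9805),
)

#: the (network, condition) entries reported as significant after FDR
SIGNIFICANT_ENTRIES = (("SMN", "rest"), ("VN", "task"), ("DMN", "task"))
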