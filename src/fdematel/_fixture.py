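"""Embedded study data: the 14-criterion health-promotion social-marketing case.

Holds the published aggregated normalized fuzzy direct-relation matrix
(14x14 triples, criteria C1..C14), the published defuzzified total-relation
matrix, and the published per-criterion D / R / D+R / D-R indices, all
transcribed at the source's 3-decimal precision.  Three cells of the fuzzy
matrix carry typesetting defects in the published tables; the repaired
values are embedded here and every repair is documented in ``REPAIRS``.
"""

from __future__ import annotations

CRITERIA: list[str] = [f"C{i}" for i in range(1, 15)]

CRITERION_NAMES: dict[str, str] = {
    "C1": "Marketing mix elements",
    "C2": "Appropriate media",
    "C3": "Designing effective communication message",
    "C4": "Feedback system",
    "C5": "Meeting the needs of beneficiaries",
    "C6": "Providing more benefit than cost",
    "C7": "Consumer orientation",
    "C8": "Long-term planning",
    "C9": "Operation process",
    "C10": "Information resources",
    "C11": "Market selection",
    "C12": "Moderate research",
    "C13": "Monitoring and adjustment",
    "C14": "Organizational advantage",
}

# Aggregated normalized fuzzy direct-relation matrix; row i, column j holds
# the (l, m, u) influence of criterion i on criterion j.  Rows C1..C14,
# cells separated by '|', components by ','.
AGGREGATED_TRIPLES = """\
0,0,0|0.036,0.056,0.071|0.038,0.056,0.071|0.034,0.053,0.066|0.026,0.045,0.062|0.029,0.046,0.061|0.037,0.057,0.071|0.044,0.063,0.075|0.041,0.058,0.07|0.045,0.065,0.075|0.034,0.054,0.068|0.031,0.049,0.065|0.029,0.048,0.066|0.022,0.04,0.059
0.034,0.052,0.068|0,0,0|0.026,0.046,0.065|0.029,0.049,0.068|0.027,0.048,0.064|0.038,0.057,0.071|0.029,0.049,0.068|0.045,0.065,0.078|0.032,0.051,0.066|0.036,0.056,0.069|0.023,0.044,0.061|0.037,0.058,0.071|0.029,0.049,0.068|0.036,0.056,0.073
0.03,0.05,0.066|0.041,0.061,0.076|0,0,0|0.041,0.061,0.075|0.037,0.057,0.074|0.029,0.049,0.066|0.028,0.049,0.066|0.038,0.056,0.072|0.031,0.048,0.063|0.03,0.05,0.067|0.028,0.049,0.066|0.034,0.054,0.071|0.039,0.06,0.075|0.03,0.05,0.067
0.031,0.052,0.069|0.029,0.049,0.069|0.029,0.049,0.069|0,0,0|0.031,0.048,0.066|0.027,0.046,0.064|0.038,0.058,0.075|0.034,0.054,0.073|0.036,0.056,0.07|0.02,0.04,0.061|0.032,0.052,0.069|0.028,0.049,0.069|0.032,0.052,0.071|0.034,0.051,0.07
0.038,0.058,0.07|0.043,0.063,0.077|0.031,0.051,0.068|0.027,0.047,0.066|0,0,0|0.037,0.057,0.074|0.039,0.059,0.074|0.032,0.052,0.069|0.042,0.062,0.075|0.036,0.057,0.072|0.035,0.056,0.071|0.034,0.055,0.07|0.033,0.053,0.07|0.039,0.059,0.074
0.039,0.059,0.073|0.021,0.04,0.059|0.035,0.056,0.069|0.034,0.054,0.069|0.031,0.049,0.066|0,0,0|0.037,0.057,0.073|0.037,0.057,0.072|0.034,0.053,0.066|0.036,0.056,0.071|0.034,0.054,0.069|0.032,0.051,0.066|0.039,0.059,0.073|0.046,0.067,0.078
0.027,0.044,0.061|0.026,0.042,0.061|0.038,0.058,0.073|0.02,0.04,0.059|0.034,0.053,0.066|0.029,0.05,0.068|0,0,0|0.033,0.054,0.071|0.034,0.054,0.071|0.027,0.047,0.064|0.031,0.051,0.07|0.022,0.042,0.062|0.027,0.045,0.061|0.03,0.051,0.066
0.023,0.04,0.057|0.022,0.042,0.062|0.032,0.052,0.069|0.026,0.046,0.063|0.026,0.044,0.061|0.028,0.048,0.067|0.038,0.058,0.073|0,0,0|0.026,0.043,0.061|0.021,0.038,0.056|0.03,0.048,0.065|0.033,0.053,0.072|0.027,0.046,0.063|0.031,0.051,0.068
0.025,0.044,0.061|0.031,0.051,0.068|0.03,0.051,0.068|0.017,0.037,0.056|0.029,0.048,0.065|0.022,0.042,0.063|0.027,0.048,0.065|0.028,0.048,0.065|0,0,0|0.033,0.053,0.068|0.034,0.055,0.067|0.031,0.052,0.067|0.028,0.048,0.067|0.024,0.045,0.063
0.023,0.04,0.059|0.027,0.048,0.066|0.039,0.06,0.075|0.036,0.055,0.068|0.02,0.039,0.059|0.029,0.049,0.066|0.039,0.06,0.076|0.039,0.058,0.073|0.032,0.052,0.071|0,0,0|0.034,0.053,0.068|0.024,0.041,0.06|0.035,0.053,0.07|0.025,0.044,0.062
0.036,0.054,0.068|0.04,0.06,0.072|0.038,0.058,0.075|0.036,0.057,0.07|0.031,0.049,0.068|0.026,0.044,0.061|0.027,0.048,0.066|0.023,0.044,0.062|0.027,0.047,0.068|0.026,0.046,0.065|0,0,0|0.025,0.046,0.066|0.033,0.053,0.072|0.031,0.051,0.07
0.039,0.058,0.073|0.024,0.043,0.059|0.039,0.059,0.075|0.034,0.055,0.07|0.028,0.049,0.067|0.029,0.046,0.061|0.038,0.058,0.073|0.028,0.049,0.068|0.03,0.05,0.069|0.027,0.047,0.066|0.034,0.053,0.07|0,0,0|0.034,0.054,0.071|0.039,0.059,0.074
0.042,0.063,0.075|0.036,0.053,0.067|0.018,0.039,0.059|0.022,0.039,0.058|0.037,0.057,0.072|0.026,0.046,0.064|0.029,0.047,0.064|0.025,0.046,0.066|0.027,0.045,0.064|0.028,0.049,0.067|0.023,0.042,0.063|0.024,0.044,0.064|0,0,0|0.031,0.051,0.069
0.04,0.06,0.073|0.022,0.041,0.059|0.037,0.057,0.072|0.025,0.045,0.066|0.029,0.049,0.068|0.023,0.044,0.062|0.034,0.052,0.069|0.032,0.051,0.069|0.033,0.052,0.067|0.039,0.06,0.076|0.035,0.056,0.074|0.024,0.041,0.059|0.027,0.044,0.061|0,0,0
"""

# Documented transcription repairs of typesetting defects in the published
# fuzzy matrix (cell -> (printed text, repaired triple, rationale)).
REPAIRS: list[dict[str, object]] = [
    {
        "cell": ("C2", "C5"),
        "printed": "{0.027, 0.048, 0.064}",
        "repaired": (0.027, 0.048, 0.064),
        "note": "braces typeset in place of parentheses; value unchanged",
    },
    {
        "cell": ("C11", "C7"),
        "printed": "(0.0270.048, 0.066)",
        "repaired": (0.027, 0.048, 0.066),
        "note": "missing comma between l and m; split so l <= m <= u holds "
                "and the column magnitude pattern is preserved",
    },
    {
        "cell": ("C2", "C14"),
        "printed": "0(.036, 0.056, 0.073)",
        "repaired": (0.036, 0.056, 0.073),
        "note": "opening parenthesis misplaced after the leading zero",
    },
]

# Published defuzzified total-relation matrix (rows C1..C14).
EXPECTED_TPRIME = """\
0.194 0.243 0.254 0.238 0.232 0.231 0.255 0.260 0.249 0.252 0.244 0.236 0.242 0.236
0.243 0.192 0.245 0.236 0.235 0.241 0.250 0.262 0.244 0.246 0.236 0.243 0.243 0.251
0.245 0.252 0.206 0.249 0.247 0.238 0.252 0.259 0.245 0.246 0.245 0.244 0.256 0.249
0.242 0.239 0.248 0.189 0.236 0.231 0.256 0.253 0.247 0.233 0.244 0.237 0.246 0.247
0.257 0.259 0.260 0.243 0.200 0.251 0.268 0.262 0.263 0.257 0.257 0.250 0.257 0.263
0.253 0.235 0.257 0.244 0.241 0.192 0.260 0.260 0.249 0.251 0.250 0.242 0.255 0.263
0.228 0.225 0.247 0.219 0.230 0.227 0.194 0.244 0.238 0.230 0.235 0.222 0.231 0.236
0.221 0.221 0.238 0.221 0.221 0.222 0.244 0.190 0.225 0.220 0.229 0.229 0.228 0.234
0.224 0.229 0.237 0.213 0.224 0.218 0.235 0.236 0.185 0.232 0.233 0.227 0.231 0.229
0.229 0.233 0.252 0.236 0.224 0.230 0.254 0.252 0.241 0.191 0.240 0.226 0.243 0.236
0.242 0.244 0.253 0.239 0.235 0.227 0.245 0.242 0.239 0.236 0.193 0.232 0.245 0.244
0.249 0.234 0.258 0.241 0.237 0.232 0.258 0.250 0.245 0.241 0.247 0.192 0.249 0.254
0.243 0.233 0.230 0.219 0.234 0.223 0.239 0.238 0.231 0.233 0.228 0.224 0.192 0.237
0.245 0.228 0.251 0.229 0.233 0.226 0.249 0.247 0.241 0.247 0.244 0.227 0.236 0.195
"""

# Published per-criterion indices: criterion -> (D, R, D+R, D-R).
EXPECTED_INDICES: dict[str, tuple[float, float, float, float]] = {
    "C1": (3.367, 3.315, 6.682, 0.051),
    "C2": (3.367, 3.268, 6.635, 0.098),
    "C3": (3.432, 3.436, 6.868, -0.005),
    "C4": (3.349, 3.215, 6.564, 0.134),
    "C5": (3.546, 3.230, 6.775, 0.316),
    "C6": (3.453, 3.189, 6.642, 0.264),
    "C7": (3.207, 3.459, 6.666, -0.252),
    "C8": (3.141, 3.453, 6.594, -0.312),
    "C9": (3.153, 3.343, 6.496, -0.190),
    "C10": (3.286, 3.314, 6.601, -0.028),
    "C11": (3.316, 3.326, 6.641, -0.010),
    "C12": (3.385, 3.231, 6.616, 0.155),
    "C13": (3.206, 3.352, 6.558, -0.146),
    "C14": (3.298, 3.373, 6.671, -0.075),
}

# Published prominence ranking (most to least important).
EXPECTED_RANKING: list[str] = [
    "C3", "C5", "C1", "C14", "C7", "C6", "C11",
    "C2", "C12", "C10", "C8", "C4", "C13", "C9",
]

# Criteria whose published D-R is strictly positive (the cause group).
EXPECTED_CAUSE_GROUP: set[str] = {"C1", "C2", "C4", "C5", "C6", "C12"}
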