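# fdematel

Fuzzy DEMATEL (decision-making trial and evaluation laboratory) analysis of
expert influence judgments, built for multi-criteria decision problems in
which a panel of experts rates, in words, how strongly each criterion
influences each other criterion. The package turns those linguistic ratings
into a total-relation matrix, ranks the criteria by overall involvement, and
partitions them into a *cause* group (net drivers of the system) and an
*effect* group (net receivers). It ships with the published 14-criterion
case study on social-marketing success criteria for health promotion as an
embedded, fully reproducible fixture, and a seeded synthetic-panel generator
so every stage can be tested without external data.

Intended users: decision analysts and health-promotion / social-marketing
researchers who need a tested, scriptable F-DEMATEL implementation rather
than a spreadsheet.

## Method

Each expert k compares n criteria pairwise on a five-level linguistic scale
mapped to triangular fuzzy numbers (l, m, u):

| term                | (l, m, u)          |
|---------------------|--------------------|
| No influence        | (0.00, 0.00, 0.25) |
| Very low influence  | (0.00, 0.25, 0.50) |
| Low influence       | (0.25, 0.50, 0.75) |
| High influence      | (0.50, 0.75, 1.00) |
| Very high influence | (0.75, 1.00, 1.00) |

giving an initial direct-relation fuzzy matrix Z⁽ᵏ⁾ with zero diagonal.
Each Z⁽ᵏ⁾ is normalized by r⁽ᵏ⁾ = maxᵢ Σⱼ uᵢⱼ⁽ᵏ⁾, the normalized matrices
are averaged componentwise over the panel, and the total-relation fuzzy
matrix is computed per component C ∈ {L, M, U} as

    T_C = C + C² + C³ + … = C (I − C)⁻¹,

which accumulates direct plus all indirect influence paths (the series
converges because the spectral radius of each component is below 1; this is
checked, not assumed). Each fuzzy cell is collapsed to a crisp value by the
best non-fuzzy performance (BNP) defuzzification T′ᵢⱼ = (l + m + u)/3. Row
sums D (influence dispatched) and column sums R (influence received) yield:

- **prominence** Dᵢ + Rᵢ — how involved criterion i is overall (ranking key);
- **relation** Dᵢ − Rᵢ — positive ⇒ cause (net driver), negative ⇒ effect.

The (D+R, D−R) pairs are the coordinates of the cause–effect diagram.

## Worked example

Analyze the embedded case study (14 social-marketing success criteria,
C1 = marketing mix elements … C14 = organizational advantage) and write the
result tables at 3-decimal display precision:

```bash
fdematel run --fixture --out demo --precision 3
```

prints

```
cause group:  C1, C2, C4, C5, C6, C12
effect group: C3, C7, C8, C9, C10, C11, C13, C14
ranking:      C3 > C5 > C1 > C7 > C14 > C11 > C2 > C6 > C12 > C10 > C8 > C4 > C13 > C9
```

and `demo/indices.csv` begins

```
,D,R,D+R,D-R,group
C1,3.358,3.315,6.673,0.043,cause
C2,3.363,3.261,6.624,0.102,cause
C3,3.423,3.428,6.851,-0.005,effect
C4,3.341,3.209,6.550,0.133,cause
C5,3.538,3.221,6.759,0.317,cause
```

Reading: C3 (designing an effective communication message) is the most
prominent criterion (D+R = 6.851) but a slight net receiver (D−R = −0.005),
while C5 (meeting the needs of beneficiaries) is the strongest net driver
(D−R = 0.317). Six criteria form the cause group — improving those
propagates through the whole system. Mid-ranking order among near-tied
criteria (prominence gaps < 0.001) is sensitive to the 3-decimal rounding of
the published input matrix; see `docs/methods.md`.

The same analysis from Python:

```python
from fdematel import load_liao_fixture, run_pipeline

bundle = load_liao_fixture()
result = run_pipeline(bundle.aggregated, criteria=bundle.criteria)
print(result.cause_group)      # ('C1', 'C2', 'C4', 'C5', 'C6', 'C12')
print(result.index_table().round(3))
```

Other entry points: `fdematel reproduce` recomputes the embedded case and
compares every cell and index against the published tables (non-zero exit
on any tolerance breach); `fdematel simulate --n 14 --p 12 --noise 0.2
--seed 7 --plant-driver C5` generates a seeded synthetic panel with a
planted driver criterion and reports whether the analysis recovers it.

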