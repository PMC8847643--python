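# opaplan

Volume-based optimal-partial-arc (OPA) angle planning for lung-sparing
VMAT of mediastinal targets, with a digital thorax phantom, a simple
arc-dose simulator and the full set of plan-quality metrics (DVH,
V_x/D_x, HI, CI, OAR constraints, gamma index).

## The problem and the algorithm

Full-rotation VMAT of an esophageal/mediastinal target bathes almost the
entire lung in low dose; lung V5 (the relative lung volume receiving at
least 5 Gy) is a key pneumonitis risk factor. Restricting the gantry to
anterior and posterior sectors spares the lateral lungs — but the right
total span theta_A is patient-specific. The volume-based algorithm
computes it from six measurements: the transverse thorax diameter T,
the PTV width E and length Lt, the whole-lung volume V_W, the
out-of-field lung volume V_OW, and the lung-V5 goal (default 55%).
With the lateral restricted-region radius

    R = (T - E - 4) / 2                                  [cm]

the unirradiated lung is modeled as a partial cylinder and the span
solves, in closed form,

    pi R^2 (360 - theta_A)/360 (Lt + 4) + V_OW = V_W (1 - expected_V5)

theta_A is then split into six deliverable partial arcs (three CW, three
CCW over the anterior sector (-theta_A/4, theta_A/4) and the posterior
sector (180 -/+ theta_A/4)) that never cross the gantry's 180-degree
rotation limit; the baseline alternative is two full 359-degree arcs.
`docs/methods.md` describes the model, its assumptions and its limits.

Intended users: medical-physics researchers studying arc-angle selection
and anyone needing a self-contained, fully testable VMAT-planning toy
chain (phantom -> geometry -> angle -> arcs -> dose -> metrics).

## Worked example

Solve the arc angle for a thorax of diameter 30 cm with a 6 x 16 cm PTV
and 4.5 L of lung:

```sh
$ opaplan opa -T 30 -E 6 -L 16 --lung-volume-cm3 4500
{
  "R_cm": 10.0,
  "achieved_geometric_v5": 0.55,
  "feasible": "OK",
  "theta_a_deg": 243.97604648600833
}
```

R = (30 - 6 - 4)/2 = 10 cm, and a 244-degree total span is predicted to
hold lung V5 at 55%. Sequencing the published sample case theta_A = 110:

```sh
$ opaplan arcs --theta-a 110
OPA plan (6 arcs)
 arc    start     stop   dir     span  collim
   1    180.0    207.5    CW     27.5     0.0
   2    332.5     27.5    CW     55.0     0.0
   3    152.5    179.0    CW     26.5     0.0
   4    179.0    152.5   CCW     26.5     5.0
   5     27.5    332.5   CCW     55.0     5.0
   6    207.5    180.0   CCW     27.5     5.0
```

Each rotation sense covers 109 degrees: the anterior and posterior
sectors (27.5 + 55 + 27.5) minus the 1-degree sentinel before 180. The
full pipeline — build the default phantom, measure it, solve, simulate
both plan types and compare:

```sh
$ opaplan run --seed 1
{
  "delta_lung_v5_pp": -14.786085951050296,
  "feasible": "OK",
  "lung_v5_fa_pct": 92.16612063981499,
  "lung_v5_opa_pct": 77.3800346887647,
  "theta_a_deg": 261.921697297247
}
```

On this phantom the personalized partial-arc plan lowers simulated lung
V5 by 14.8 percentage points relative to the two-full-arc baseline.
(The toy dose model has no scatter or inverse optimization, so absolute
V5 values run higher than clinical plans; the FA-vs-OPA *ordering* is
the meaningful output.) Add `--out <dir>` to write plan JSON, DVH CSVs,
a comparison table and a byte-reproducible `report.json`.

The same operations are available as a library:

```python
import opaplan as op

geom = op.GeometryInputs(T=30, E=6, Lt=16, V_W=4500, V_OW=0, expected_v5=0.55)
res = op.solve_opa_angle(geom)          # res.theta_a -> 243.976...
plan = op.sequence_opa_arcs(res.theta_a)
structs = op.build_thorax_phantom(op.PhantomSpec())
dose = op.simulate_dose(structs, plan)
report = op.plan_report(dose, structs, "OPA")
```

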