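# pestiscreen

Tiered structure-to-process screening and redesign support for pesticides.

Most registered pesticides carry cores that are oxidizable by
photochemically produced reactive intermediates (PPRIs) in sunlit surface
waters — phenols, anilines, aryl ethers, sulfides, thiols — and their
environmental fate is largely set by electron transfer to excited
triplet-state chromophoric dissolved organic matter (³CDOM\*). At the same
time, their aquatic hazard tracks two cheap descriptors: the octanol–water
distribution coefficient at pH 7.4 (log *D*<sub>o/w</sub>, bioavailability)
and the HOMO–LUMO gap (Δ*E*, covalent reactivity). `pestiscreen` wires
these threads into one screening tool for chemists and risk assessors who
want to rank existing pesticides — or candidate analogs — on
photodegradability, ecotoxicity, and retained performance, starting from
nothing more than precomputed orbital energies and log *D*.

## The model

For a pesticide *i* and a sensitizer *s* in a ³CDOM\* panel:

- driving force: ΔG⁰<sub>et</sub> = a·(E<sub>SOMO,s</sub> − E<sub>HOMO,i</sub>) + b  (gap in eV, ΔG in kcal/mol);
- Marcus barrier: ΔG‡ = (λ + ΔG⁰<sub>et</sub>)² / 4λ, with reorganization energy λ (default 35 kcal/mol);
- kinetics: log *k* = c·ΔG‡ + d, capped at the diffusion limit (default log *k* = 9.7).

Pairwise predictions are averaged over the panel ("mixture-like" behavior),
and each compound receives a composite 0–100 score: the mean of its
percentile on mixture-mean log *k* and its percentile on −ΔG⁰<sub>et</sub>
within the screened population. Hazard is scored by the **rule of 2**
(safer chemical space: log *D* < 1.7 **and** Δ*E* > 6 eV, strict), the
**Briggs Rule of 3** (log *D* < 3, the efficacy/safety balance for active
ingredients), the percentile of E<sub>LUMO</sub> within a no/low-concern
reference distribution, and inclusive per-category performance bounds over
(log *D*, Δ*E*) for five functional classes and seven modes of action.
At the substructural tier, summed natural-bond-orbital stabilization
energies Σ*E*(2) > 24 kcal/mol flag substituent patterns with good
photodegradation propensity, and the total Hirshfeld ring charge predicts
ΔG⁰<sub>et</sub> = 146.62·Σ<sub>r</sub>X<sub>C</sub> − 38.89 (kcal/mol).

See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

Screen a halogenated, lipophilic parent against an amine-substituted
analog inside a 200-compound synthetic reference population:

```python
from pestiscreen import (Compound, GeneratorParams, generate, screen,
                         compare_redesign, format_percentile)

parent = Compound(id="parent", smiles="COc1cc(Cl)ccc1O",
                  e_homo=-6.40, e_lumo=-0.34, log_d=4.64)
analog = Compound(id="analog", smiles="COc1cc(N)ccc1O",
                  e_homo=-5.80, e_lumo=-0.34, log_d=1.61)

data = generate(GeneratorParams(n=200, seed=0))
report = screen(data.compounds + [parent, analog], data.panel)
for cid in ("parent", "analog"):
    r = report.row(cid)
    print(f"{cid}: score={r.score:.1f} bracket={r.bracket} "
          f"safe={r.in_safe_space} briggs={r.briggs_ok} "
          f"E_LUMO pct={format_percentile(r.elumo_percentile)}")
delta = compare_redesign(report.row("parent"), report.row("analog"))
print(f"redesign: d_log_d={delta.d_log_d:+.2f} "
      f"d_score={delta.d_composite_score:+.1f}")
```

prints

```
parent: score=20.9 bracket=<50th safe=False briggs=False E_LUMO pct=55th
analog: score=66.2 bracket=50-74th safe=False briggs=True E_LUMO pct=55th
redesign: d_log_d=-3.03 d_score=+45.3
```

The parent sits in the bottom half of the photodegradation ranking and
fails the Briggs rule; raising the HOMO (electron-donating amine) moves the
analog to the 66th composite percentile, and the 3-unit log *D* drop brings
it inside Briggs — but neither compound reaches the safer chemical space,
which also requires Δ*E* > 6 eV. E<sub>LUMO</sub> is unchanged by design,
so its safety percentile does not move.

The same pipeline is available from the shell:

```bash
pestiscreen generate --n 700 --seed 0 --out data/
pestiscreen screen --compounds data/compounds.csv --panel data/panel.csv --out out/
pestiscreen brackets --screen-report out/screen.json --outside-safe-only --out out/
```

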