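# SYNTHETIC density map: HIV-specialists per 10,000 gay men by federal state.
#
# Only the three city states' densities are published (Berlin 10.27,
# Hamburg 10.73, Bremen 12.73); the remaining values here are synthetic
# placeholders chosen to mirror the described pattern (east German states
# lower, city states highest) for simulation and testing.  Replace with a
# real map for any substantive analysis.
densities:
  "Baden-Wuerttemberg": 6.5
  "Bavaria": 7.2
  "Berlin": 10.27
  "Brandenburg": 1.4
  "Bremen": 12.73
  "Hamburg": 10.73
  "Hesse": 7.8
  "Mecklenburg Western Pomerania": 0.8
  "Lower Saxony": 4.2
  "North Rhine-Westphalia": 6.8
  "Rhineland-Palatinate": 3.6
  "Saarland": 4.8
  "Saxony": 2.2
  "Saxony-Anhalt": 1.1
  "Schleswig-Holstein": 1.8
  "Thuringia": 1.6
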