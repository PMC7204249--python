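# Default antipsychotic dose-equivalence tables.
#
# ddd:               mg per defined daily dose (WHO ATC/DDD convention);
#                    a daily dose in mg is DIVIDED by this entry to give DDDs.
# olanzapine_eq:     mg olanzapine-equivalent per mg of drug (dose is multiplied).
# chlorpromazine_eq: mg chlorpromazine-equivalent per mg of drug (dose is multiplied).
#
# Factor values are literature-typical oral maintenance equivalences and are
# user-editable; which drugs each method covers (its coverage set) is the part
# of this file the package pins in its tests. A drug absent from a method's
# block is NOT convertible by that method — it never silently converts to zero.

ddd:
  amisulpride: 400
  aripiprazole: 15
  chlorprothixene: 300
  clozapine: 300
  flupentixol: 6
  haloperidol: 8
  levomepromazine: 300
  melperone: 300
  olanzapine: 10
  paliperidone: 6
  penfluridol: 6
  perphenazine: 30
  pimozide: 4
  prochlorperazine: 100
  quetiapine: 400
  risperidone: 5
  sertindole: 16
  sulpiride: 800
  thioridazine: 300
  ziprasidone: 80
  zuclopenthixol: 30

olanzapine_eq:
  amisulpride: 0.025
  aripiprazole: 0.667
  chlorprothixene: 0.033
  clozapine: 0.033
  flupentixol: 1.667
  haloperidol: 1.25
  levomepromazine: 0.033
  olanzapine: 1.0
  paliperidone: 1.667
  perphenazine: 0.333
  pimozide: 2.5
  prochlorperazine: 0.1
  quetiapine: 0.025
  risperidone: 2.0
  sertindole: 0.625
  sulpiride: 0.0125
  thioridazine: 0.033
  ziprasidone: 0.125
  zuclopenthixol: 0.333

chlorpromazine_eq:
  aripiprazole: 13.3
  clozapine: 2.0
  haloperidol: 50.0
  olanzapine: 20.0
  perphenazine: 12.5
  quetiapine: 1.33
  risperidone: 50.0
  thioridazine: 1.0
  ziprasidone: 1.67
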