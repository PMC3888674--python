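# Oral antipsychotics screened by the pipeline.
#
# class:       typical (first-generation) or atypical (second-generation)
# cpz_factor:  mg chlorpromazine-equivalent per mg of drug, i.e. a prescribed
#              daily dose of D mg counts as D * cpz_factor mg chlorpromazine.
#              Factors follow widely used consensus equivalence tables
#              (approximate clinical equivalents of chlorpromazine 100 mg/day);
#              they are deliberately editable: replace this file (or pass an
#              override table) to use a different equivalence standard.
atypical:
  amisulpride:    {cpz_factor: 1.0}     # 100 mg  ~ CPZ 100 mg
  aripiprazole:   {cpz_factor: 13.3}    # 7.5 mg  ~ CPZ 100 mg
  clozapine:      {cpz_factor: 2.0}     # 50 mg   ~ CPZ 100 mg
  olanzapine:     {cpz_factor: 20.0}    # 5 mg    ~ CPZ 100 mg
  paliperidone:   {cpz_factor: 33.3}    # 3 mg    ~ CPZ 100 mg
  quetiapine:     {cpz_factor: 1.33}    # 75 mg   ~ CPZ 100 mg
  risperidone:    {cpz_factor: 50.0}    # 2 mg    ~ CPZ 100 mg
  sertindole:     {cpz_factor: 25.0}    # 4 mg    ~ CPZ 100 mg
  zotepine:       {cpz_factor: 1.33}    # 75 mg   ~ CPZ 100 mg
typical:
  benperidol:     {cpz_factor: 100.0}   # 1 mg    ~ CPZ 100 mg
  chlorpromazine: {cpz_factor: 1.0}     # reference compound
  chlorprothixene: {cpz_factor: 2.0}
  droperidol:     {cpz_factor: 25.0}
  flupentixol:    {cpz_factor: 33.3}    # 3 mg    ~ CPZ 100 mg
  fluphenazine:   {cpz_factor: 50.0}    # 2 mg    ~ CPZ 100 mg
  haloperidol:    {cpz_factor: 50.0}    # 2 mg    ~ CPZ 100 mg
  levomepromazine: {cpz_factor: 1.0}
  loxapine:       {cpz_factor: 10.0}
  oxypertine:     {cpz_factor: 10.0}
  pericyazine:    {cpz_factor: 10.0}
  perphenazine:   {cpz_factor: 12.5}    # 8 mg    ~ CPZ 100 mg
  pimozide:       {cpz_factor: 50.0}
  promazine:      {cpz_factor: 1.0}
  remoxipride:    {cpz_factor: 0.67}
  sulpiride:      {cpz_factor: 0.5}     # 200 mg  ~ CPZ 100 mg
  thioridazine:   {cpz_factor: 1.0}
  trifluoperazine: {cpz_factor: 20.0}   # 5 mg    ~ CPZ 100 mg
  trifluperidol:  {cpz_factor: 100.0}
  zuclopenthixol: {cpz_factor: 4.0}     # 25 mg   ~ CPZ 100 mg
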