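brand,generic
lasix,furosemide
coumadin,warfarin
tylenol,acetaminophen
advil,ibuprofen
motrin,ibuprofen
aleve,naproxen
prilosec,omeprazole
nexium,esomeprazole
protonix,pantoprazole
prevacid,lansoprazole
zocor,simvastatin
lipitor,atorvastatin
crestor,rosuvastatin
glucophage,metformin
synthroid,levothyroxine
benadryl,diphenhydramine
ativan,lorazepam
xanax,alprazolam
valium,diazepam
ambien,zolpidem
restoril,temazepam
plavix,clopidogrel
eliquis,apixaban
xarelto,rivaroxaban
norvasc,amlodipine
toprol,metoprolol
lopressor,metoprolol
prinivil,lisinopril
zestril,lisinopril
cozaar,losartan
diovan,valsartan
lanoxin,digoxin
cordarone,amiodarone
neurontin,gabapentin
lyrica,pregabalin
zoloft,sertraline
prozac,fluoxetine
celexa,citalopram
lexapro,escitalopram
cymbalta,duloxetine
effexor,venlafaxine
remeron,mirtazapine
celebrex,celecoxib
mobic,meloxicam
flomax,tamsulosin
ditropan,oxybutynin
zantac,ranitidine
pepcid,famotidine
tums,calcium carbonate
colace,docusate
miralax,polyethylene glycol
imodium,loperamide
zofran,ondansetron
reglan,metoclopramide
aricept,donepezil
namenda,memantine
deltasone,prednisone
decadron,dexamethasone
ultram,tramadol
oxycontin,oxycodone
dilaudid,hydromorphone
ventolin,albuterol
spiriva,tiotropium
singulair,montelukast
claritin,loratadine
zyrtec,cetirizine
antivert,meclizine
vitamin b12,cyanocobalamin
vitamin d3,cholecalciferol
vitamin d2,ergocalciferol
vitamin c,ascorbic acid
vitamin e,alpha-tocopherol
vitamin b1,thiamine
vitamin b6,pyridoxine
slow-k,potassium chloride
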