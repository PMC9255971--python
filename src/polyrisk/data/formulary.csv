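generic_name,atc_codes,primary_index
atorvastatin,C10AA05,0
simvastatin,C10AA01,0
rosuvastatin,C10AA07,0
pravastatin,C10AA03,0
ezetimibe,C10AX09,0
gemfibrozil,C10AB04,0
fish oil,C10AX06,0
lisinopril,C09AA03,0
enalapril,C09AA02,0
ramipril,C09AA05,0
losartan,C09CA01,0
valsartan,C09CA03,0
olmesartan,C09CA08,0
metoprolol,C07AB02,0
atenolol,C07AB03,0
bisoprolol,C07AB07,0
carvedilol,C07AG02,0
propranolol,C07AA05,0
sotalol,C07AA07,0
amlodipine,C08CA01,0
nifedipine,C08CA05,0
diltiazem,C08DB01,0
verapamil,C08DA01,0
furosemide,C03CA01,0
bumetanide,C03CA02,0
hydrochlorothiazide,C03AA03,0
chlorthalidone,C03BA04,0
spironolactone,C03DA01,0
triamterene,C03DB02,0
digoxin,C01AA05,0
amiodarone,C01BD01,0
isosorbide mononitrate,C01DA14,0
nitroglycerin,C01DA02,0
coenzyme q10,C01EB09,0
clonidine,C02AC01,0
hydralazine,C02DB02,0
doxazosin,C02CA04,0
warfarin,B01AA03,0
clopidogrel,B01AC04,0
aspirin,B01AC06;N02BA01,0
apixaban,B01AF02,0
rivaroxaban,B01AF01,0
enoxaparin,B01AB05,0
metformin,A10BA02,0
glipizide,A10BB07,0
glimepiride,A10BB12,0
sitagliptin,A10BH01,0
empagliflozin,A10BK03,0
insulin glargine,A10AE04,0
omeprazole,A02BC01,0
pantoprazole,A02BC02,0
esomeprazole,A02BC05,0
lansoprazole,A02BC03,0
famotidine,A02BA03,0
ranitidine,A02BA02,0
calcium carbonate,A12AA04;A02AC01,0
magnesium oxide,A12CC10,0
potassium chloride,A12BA01,0
ferrous sulfate,B03AA07,0
cyanocobalamin,B03BA01,0
folic acid,B03BB01,0
multivitamin,A11BA01,0
cholecalciferol,A11CC05,0
ergocalciferol,A11CC01,0
ascorbic acid,A11GA01,0
alpha-tocopherol,A11HA03,0
thiamine,A11DA01,0
pyridoxine,A11HA02,0
levothyroxine,H03AA01,0
prednisone,H02AB07,0
dexamethasone,H02AB02,0
sertraline,N06AB06,0
citalopram,N06AB04,0
escitalopram,N06AB10,0
fluoxetine,N06AB03,0
amitriptyline,N06AA09,0
nortriptyline,N06AA10,0
mirtazapine,N06AX11,0
trazodone,N06AX05,0
duloxetine,N06AX21,0
venlafaxine,N06AX16,0
bupropion,N06AX12,0
st johns wort,N06AX25,0
gabapentin,N03AX12,0
pregabalin,N03AX16,0
levetiracetam,N03AX14,0
lorazepam,N05BA06,0
alprazolam,N05BA12,0
diazepam,N05BA01,0
clonazepam,N03AE01,0
temazepam,N05CD07,0
zolpidem,N05CF02,0
quetiapine,N05AH04,0
olanzapine,N05AH03,0
melatonin,N05CH01,0
hydroxyzine,N05BB01,0
donepezil,N06DA02,0
memantine,N06DX01,0
ginkgo biloba,N06DX02,0
tramadol,N02AX02,0
oxycodone,N02AA05,0
morphine,N02AA01,0
hydromorphone,N02AA04,0
acetaminophen,N02BE01,0
ibuprofen,M01AE01,0
naproxen,M01AE02,0
celecoxib,M01AH01,0
meloxicam,M01AC06,0
diclofenac,M01AB05,0
glucosamine,M01AX05,0
allopurinol,M04AA01,0
cyclobenzaprine,M03BX08,0
tamsulosin,G04CA02,0
finasteride,G04CB01,0
saw palmetto,G04CX02,0
oxybutynin,G04BD04,0
solifenacin,G04BD08,0
albuterol,R03AC02,0
tiotropium,R03BB04,0
fluticasone,R03BA05,0
montelukast,R03DC03,0
diphenhydramine,R06AA02,0
chlorpheniramine,R06AB04,0
loratadine,R06AX13,0
cetirizine,R06AE07,0
meclizine,R06AE05,0
metoclopramide,A03FA01,0
ondansetron,A04AA01,0
palonosetron,A04AA05,0
aprepitant,A04AD12,0
docusate,A06AA02,0
senna,A06AB06,0
bisacodyl,A06AB02,0
polyethylene glycol,A06AD15,0
loperamide,A07DA03,0
lactobacillus,A07FA01,0
carboplatin,L01XA02,0
cisplatin,L01XA01,0
oxaliplatin,L01XA03,0
paclitaxel,L01CD01,0
docetaxel,L01CD02,0
gemcitabine,L01BC05,0
fluorouracil,L01BC02,0
capecitabine,L01BC06,0
pemetrexed,L01BA04,0
etoposide,L01CB01,0
irinotecan,L01CE02,0
doxorubicin,L01DB01,0
cyclophosphamide,L01AA01,0
rituximab,L01FA01,0
pembrolizumab,L01FF02,0
nivolumab,L01FF01,0
bevacizumab,L01FG01,0
erlotinib,L01EB02,0
osimertinib,L01EB04,0
abiraterone,L02BX03,0
enzalutamide,L02BB04,0
letrozole,L02BG04,0
tamoxifen,L02BA01,0
leuprolide,L02AE02,0
filgrastim,L03AA02,0
pegfilgrastim,L03AA13,0
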