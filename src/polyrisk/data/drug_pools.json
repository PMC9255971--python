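{
  "otc": [
    "omeprazole", "esomeprazole", "lansoprazole", "famotidine", "ranitidine",
    "calcium carbonate", "magnesium oxide", "ferrous sulfate",
    "cyanocobalamin", "folic acid", "multivitamin", "cholecalciferol",
    "ergocalciferol", "ascorbic acid", "alpha-tocopherol", "thiamine",
    "pyridoxine", "acetaminophen", "ibuprofen", "naproxen",
    "diphenhydramine", "chlorpheniramine", "loratadine", "cetirizine",
    "meclizine", "docusate", "senna", "bisacodyl", "polyethylene glycol",
    "loperamide", "aspirin"
  ],
  "complementary": [
    "fish oil", "coenzyme q10", "st johns wort", "ginkgo biloba",
    "glucosamine", "saw palmetto", "melatonin", "lactobacillus",
    "turmeric", "cranberry extract"
  ],
  "cancer": [
    "carboplatin", "cisplatin", "oxaliplatin", "paclitaxel", "docetaxel",
    "gemcitabine", "fluorouracil", "capecitabine", "pemetrexed", "etoposide",
    "irinotecan", "doxorubicin", "cyclophosphamide", "rituximab",
    "pembrolizumab", "nivolumab", "bevacizumab", "erlotinib", "osimertinib",
    "abiraterone", "enzalutamide", "letrozole", "tamoxifen", "leuprolide"
  ],
  "supportive": [
    "ondansetron", "palonosetron", "aprepitant", "dexamethasone",
    "filgrastim", "pegfilgrastim"
  ]
}
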