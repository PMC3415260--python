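# Geographic gazetteer stand-in: entry<TAB>tier.
# Tiers: country (UN-recognized countries and self-proclaimed entities),
# capital (national capitals), us_place (state, state capital, largest city),
# ca_place (province/territory, capital, largest cities, tourist attractions),
# world_city (major non-capital cities elsewhere). Matching is case-sensitive
# on whole phrases.
Canada	country
United States	country
France	country
Germany	country
Italy	country
Spain	country
Portugal	country
Ireland	country
United Kingdom	country
Netherlands	country
Belgium	country
Switzerland	country
Austria	country
Poland	country
Ukraine	country
Russia	country
Sweden	country
Norway	country
Denmark	country
Finland	country
Iceland	country
Greece	country
Turkey	country
China	country
Japan	country
India	country
Pakistan	country
Bangladesh	country
Vietnam	country
Thailand	country
Philippines	country
Indonesia	country
Malaysia	country
Singapore	country
South Korea	country
Iran	country
Iraq	country
Israel	country
Lebanon	country
Jordan	country
Saudi Arabia	country
Egypt	country
Libya	country
Morocco	country
Algeria	country
Tunisia	country
Nigeria	country
Ghana	country
Kenya	country
Ethiopia	country
Somalia	country
Liberia	country
Sudan	country
South Africa	country
Zimbabwe	country
Mexico	country
Guatemala	country
Cuba	country
Haiti	country
Jamaica	country
Colombia	country
Venezuela	country
Ecuador	country
Peru	country
Bolivia	country
Chile	country
Argentina	country
Uruguay	country
Paraguay	country
Brazil	country
Australia	country
New Zealand	country
Eritrea	country
Abkhazia	country
Kosovo	country
Ottawa	capital
Washington	capital
Paris	capital
Berlin	capital
Rome	capital
Madrid	capital
Lisbon	capital
Dublin	capital
London	capital
Amsterdam	capital
Brussels	capital
Bern	capital
Vienna	capital
Warsaw	capital
Kyiv	capital
Moscow	capital
Stockholm	capital
Oslo	capital
Copenhagen	capital
Helsinki	capital
Reykjavik	capital
Athens	capital
Ankara	capital
Beijing	capital
Tokyo	capital
New Delhi	capital
Islamabad	capital
Dhaka	capital
Hanoi	capital
Bangkok	capital
Manila	capital
Jakarta	capital
Kuala Lumpur	capital
Seoul	capital
Tehran	capital
Baghdad	capital
Jerusalem	capital
Beirut	capital
Amman	capital
Riyadh	capital
Cairo	capital
Tripoli	capital
Rabat	capital
Algiers	capital
Tunis	capital
Abuja	capital
Accra	capital
Nairobi	capital
Addis Ababa	capital
Mogadishu	capital
Monrovia	capital
Khartoum	capital
Pretoria	capital
Harare	capital
Mexico City	capital
Havana	capital
Kingston	capital
Bogota	capital
Caracas	capital
Quito	capital
Lima	capital
La Paz	capital
Santiago	capital
Buenos Aires	capital
Montevideo	capital
Brasilia	capital
Canberra	capital
Wellington	capital
Alabama	us_place
Montgomery	us_place
Birmingham	us_place
Alaska	us_place
Juneau	us_place
Anchorage	us_place
Arizona	us_place
Phoenix	us_place
Arkansas	us_place
Little Rock	us_place
California	us_place
Sacramento	us_place
Los Angeles	us_place
Colorado	us_place
Denver	us_place
Connecticut	us_place
Hartford	us_place
Bridgeport	us_place
Delaware	us_place
Dover	us_place
Wilmington	us_place
Florida	us_place
Tallahassee	us_place
Jacksonville	us_place
Georgia	us_place
Atlanta	us_place
Hawaii	us_place
Honolulu	us_place
Idaho	us_place
Boise	us_place
Illinois	us_place
Springfield	us_place
Chicago	us_place
Indiana	us_place
Indianapolis	us_place
Iowa	us_place
Des Moines	us_place
Kansas	us_place
Topeka	us_place
Wichita	us_place
Kentucky	us_place
Frankfort	us_place
Louisville	us_place
Louisiana	us_place
Baton Rouge	us_place
New Orleans	us_place
Maine	us_place
Augusta	us_place
Portland	us_place
Maryland	us_place
Annapolis	us_place
Baltimore	us_place
Massachusetts	us_place
Boston	us_place
Michigan	us_place
Lansing	us_place
Detroit	us_place
Minnesota	us_place
Saint Paul	us_place
Minneapolis	us_place
Mississippi	us_place
Jackson	us_place
Missouri	us_place
Jefferson City	us_place
Kansas City	us_place
Montana	us_place
Helena	us_place
Billings	us_place
Nebraska	us_place
Lincoln	us_place
Omaha	us_place
Nevada	us_place
Carson City	us_place
Las Vegas	us_place
New Hampshire	us_place
Concord	us_place
Manchester	us_place
New Jersey	us_place
Trenton	us_place
Newark	us_place
New Mexico	us_place
Santa Fe	us_place
Albuquerque	us_place
New York	us_place
Albany	us_place
New York City	us_place
North Carolina	us_place
Raleigh	us_place
Charlotte	us_place
North Dakota	us_place
Bismarck	us_place
Fargo	us_place
Ohio	us_place
Columbus	us_place
Oklahoma	us_place
Oklahoma City	us_place
Oregon	us_place
Salem	us_place
Pennsylvania	us_place
Harrisburg	us_place
Philadelphia	us_place
Rhode Island	us_place
Providence	us_place
South Carolina	us_place
Columbia	us_place
South Dakota	us_place
Pierre	us_place
Sioux Falls	us_place
Tennessee	us_place
Nashville	us_place
Memphis	us_place
Texas	us_place
Austin	us_place
Houston	us_place
Utah	us_place
Salt Lake City	us_place
Vermont	us_place
Montpelier	us_place
Burlington	us_place
Virginia	us_place
Richmond	us_place
Virginia Beach	us_place
West Virginia	us_place
Charleston	us_place
Wisconsin	us_place
Madison	us_place
Milwaukee	us_place
Wyoming	us_place
Cheyenne	us_place
Seattle	us_place
Olympia	us_place
Ontario	ca_place
Toronto	ca_place
Mississauga	ca_place
Hamilton	ca_place
Niagara Falls	ca_place
Quebec	ca_place
Quebec City	ca_place
Montreal	ca_place
Laval	ca_place
Mont Tremblant	ca_place
British Columbia	ca_place
Victoria	ca_place
Vancouver	ca_place
Surrey	ca_place
Whistler	ca_place
Alberta	ca_place
Edmonton	ca_place
Calgary	ca_place
Banff	ca_place
Jasper	ca_place
Lake Louise	ca_place
Manitoba	ca_place
Winnipeg	ca_place
Churchill	ca_place
Saskatchewan	ca_place
Regina	ca_place
Saskatoon	ca_place
Nova Scotia	ca_place
Halifax	ca_place
Peggys Cove	ca_place
New Brunswick	ca_place
Fredericton	ca_place
Moncton	ca_place
Saint John	ca_place
Prince Edward Island	ca_place
Charlottetown	ca_place
Newfoundland	ca_place
St. John's	ca_place
Gros Morne	ca_place
Yukon	ca_place
Whitehorse	ca_place
Northwest Territories	ca_place
Yellowknife	ca_place
Nunavut	ca_place
Iqaluit	ca_place
Barcelona	world_city
Munich	world_city
Frankfurt	world_city
Hamburg	world_city
Milan	world_city
Naples	world_city
Lyon	world_city
Marseille	world_city
Manchester	world_city
Liverpool	world_city
Glasgow	world_city
Saint Petersburg	world_city
Krakow	world_city
Rotterdam	world_city
Geneva	world_city
Zurich	world_city
Porto	world_city
Istanbul	world_city
Shanghai	world_city
Guangzhou	world_city
Shenzhen	world_city
Hong Kong	world_city
Osaka	world_city
Yokohama	world_city
Mumbai	world_city
Kolkata	world_city
Chennai	world_city
Bangalore	world_city
Karachi	world_city
Lahore	world_city
Ho Chi Minh City	world_city
Busan	world_city
Alexandria	world_city
Casablanca	world_city
Lagos	world_city
Mombasa	world_city
Cape Town	world_city
Johannesburg	world_city
Durban	world_city
Guadalajara	world_city
Monterrey	world_city
Medellin	world_city
Guayaquil	world_city
Sao Paulo	world_city
Rio de Janeiro	world_city
Sydney	world_city
Melbourne	world_city
Brisbane	world_city
Perth	world_city
Auckland	world_city
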